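center,gender,month,count
nursery_school,female,10,1
nursery_school,female,11,1
nursery_school,female,20,1
nursery_school,female,24,1
nursery_school,male,10,1
nursery_school,male,14,1
nursery_school,male,18,4
nursery_school,male,24,1
nursery_school,male,25,1
nursery_school,male,26,2
nursery_school,male,27,1
nursery_school,male,30,1
nursery_school,male,32,1
nursery_school,male,37,1
psychopedagogical_center,female,9,1
psychopedagogical_center,female,15,2
psychopedagogical_center,female,18,1
psychopedagogical_center,female,19,3
psychopedagogical_center,female,26,1
psychopedagogical_center,female,27,1
psychopedagogical_center,female,28,1
psychopedagogical_center,male,15,3
psychopedagogical_center,male,16,1
psychopedagogical_center,male,18,4
psychopedagogical_center,male,19,2
psychopedagogical_center,male,20,2
psychopedagogical_center,male,24,2
psychopedagogical_center,male,25,1
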