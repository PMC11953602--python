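center,gender,band,count
nursery_school,female,<=12,10
nursery_school,female,13-24,22
nursery_school,female,25-36,31
nursery_school,male,<=12,8
nursery_school,male,13-24,24
nursery_school,male,25-36,39
psychopedagogical_center,female,<=12,5
psychopedagogical_center,female,13-24,22
psychopedagogical_center,female,25-36,9
psychopedagogical_center,male,<=12,3
psychopedagogical_center,male,13-24,34
psychopedagogical_center,male,25-36,11
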