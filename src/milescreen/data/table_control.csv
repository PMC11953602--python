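factor,center,gender,severity,count
birth_complications,nursery_school,female,warning,3
birth_complications,nursery_school,female,none,1
birth_complications,nursery_school,male,alarm,4
birth_complications,nursery_school,male,none,3
birth_complications,psychopedagogical_center,male,alarm,2
family_history,nursery_school,male,alarm,1
family_history,psychopedagogical_center,male,alarm,1
bilingual,nursery_school,female,warning,3
bilingual,nursery_school,female,none,4
bilingual,nursery_school,male,alarm,1
bilingual,nursery_school,male,none,2
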