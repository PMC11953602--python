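suggestion,gender,month,reason
refer_early_intervention,male,26,"We will monitor the situation closely. If necessary, we will consult the Early Assessment Team for guidance."
refer_early_intervention,male,18,"There are alternative forms of communication besides verbal language, and he demonstrates proficiency in them. We will observe his development and see how it progresses."
refer_early_intervention,female,10,"The questions do not align with the child's developmental stage."
refer_early_intervention,male,10,"The questions do not align with the child's developmental stage."
refer_early_intervention,female,15,"The questions do not align with the child's developmental stage."
repeat_2mo,female,12,"The questions do not align with the child's developmental stage."
repeat_2mo,male,18,"We consider that it is not necessary at this stage."
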