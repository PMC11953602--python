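suggestion,declined,accepted
refer_early_intervention,5,45
typical_development,0,125
repeat_2mo,2,29
repeat_3mo,0,44
repeat_1mo,0,20
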