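suggestion,count,pct
typical_development,117,53.7
refer_early_intervention,43,19.7
repeat_3mo,28,12.8
repeat_2mo,19,8.7
repeat_1mo,11,5.0
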