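gender,severity,count,pct
female,alarm,14,6.4
female,warning,29,13.3
female,none,56,25.9
male,alarm,29,13.3
male,warning,29,13.3
male,none,61,27.9
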