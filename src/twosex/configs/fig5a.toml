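# Case 1a, older mothers more fertile: boundary singular strategy
case = "case1a"
task = "ss-search"

[parameters]
k1 = 5.0
k2 = 15.0
Cm = 0.4
Cf = 0.6

[output]
basename = "fig5a"
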