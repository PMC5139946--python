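# Case 1a, younger mothers more fertile: boundary singular strategy
case = "case1a"
task = "ss-search"

[parameters]
k1 = 15.0
k2 = 5.0
Cm = 0.4
Cf = 0.6

[output]
basename = "fig5b"
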