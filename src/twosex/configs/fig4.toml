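# Case 1a, equal maternal reproductive rates: selectively neutral line
case = "case1a"
task = "neutral-line"

[parameters]
k1 = 10.0
k2 = 10.0
Cm = 0.4
Cf = 0.6

[numerics]
seed = 1
n_starts = 5

[output]
basename = "fig4"
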