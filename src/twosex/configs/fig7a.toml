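# Case 1b (offspring-mortality cost): neutral line with unequal rates
case = "case1b"
task = "neutral-line"

[parameters]
Cm = 0.2
Cf = 0.8
mu_f1 = 0.1
mu_f2 = 0.5
R1 = 15.0
R2 = 5.0

[numerics]
seed = 1
n_starts = 5

[output]
basename = "fig7a"
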