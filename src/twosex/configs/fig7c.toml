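# Case 1b (offspring-mortality cost): neutral line, reversed asymmetries
case = "case1b"
task = "neutral-line"

[parameters]
Cm = 0.8
Cf = 0.2
mu_f1 = 0.5
mu_f2 = 0.1
R1 = 5.0
R2 = 15.0

[numerics]
seed = 1
n_starts = 5

[output]
basename = "fig7c"
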