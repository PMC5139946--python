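# Case 2: female variance in reproductive success (investment sweep)
case = "case2"
task = "sweep"

[parameters]
c1 = 0.5

[sweep]
variable = "R1"
grid = [2.0, 15.0]
num = 8

[sweep.linked]
R2 = [30.0, -1.0]

[output]
basename = "fig8b"
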