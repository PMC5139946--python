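# Case 2: male variance in reproductive success (competitiveness sweep)
case = "case2"
task = "sweep"

[parameters]
R1 = 15.0
R2 = 15.0

[sweep]
variable = "c1"
grid = [0.05, 0.5]
num = 8

[output]
basename = "fig8a"
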