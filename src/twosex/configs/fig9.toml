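# Case 2: effect of the quality-inheritance probability q
case = "case2"
task = "sweep"

[parameters]
c1 = 0.1
R1 = 10.0
R2 = 20.0

[sweep]
variable = "q"
grid = [0.5, 0.99]
num = 8

[output]
basename = "fig9"
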