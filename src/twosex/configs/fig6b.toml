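# Case 1a singular strategies across offspring costs, k1 > k2
case = "case1a"
task = "sweep"

[parameters]
k1 = 15.0
k2 = 5.0

[sweep]
variable = "Cm"
grid = [0.15, 0.85]
num = 8

[sweep.linked]
Cf = [1.0, -1.0]

[output]
basename = "fig6b"
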