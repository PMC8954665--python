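[grain]
name = "wheat (two-phase)"

[shape]
aspect = 2.5
k = 3.0

[densities]
units = "kg/m3"
rho_s = 1470.0
rho_w = 1000.0

[dielectric]
eps_s = 3.8
eps_a = 1.0

[water]
A_s = 280.0
T = 298.0
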