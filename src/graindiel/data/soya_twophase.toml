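[grain]
name = "soya (two-phase)"

[shape]
aspect = 0.81
k = 3.0

[densities]
units = "kg/m3"
rho_s = 1340.0
rho_w = 1000.0

[dielectric]
eps_s = 4.0
eps_a = 1.0

[water]
A_s = 990.0
T = 298.0
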