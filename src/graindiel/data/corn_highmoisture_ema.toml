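# High-moisture corn, SWA/WSA effective-medium blend (M_c = 0.16).
[grain]
name = "corn (high-moisture, EMA)"

[shape]
aspect = 1.4
k = 3.0

[densities]
units = "kg/m3"
rho_s = 1450.0
rho_b = 612.0
rho_w = 1000.0

[dielectric]
eps_s = 2.5
eps_a = 1.0

[water]
A_s = 200.0
T = 298.0
M_c = 0.16
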