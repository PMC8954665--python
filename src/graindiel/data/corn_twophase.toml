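# Settled field corn, 200 MHz two-phase modeling set.
[grain]
name = "corn (two-phase)"

[shape]
aspect = 1.4
k = 3.0

[densities]
units = "kg/m3"
rho_s = 1450.0
rho_w = 1000.0

[dielectric]
eps_s = 3.3
eps_a = 1.0

[water]
A_s = 200.0
T = 298.0
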