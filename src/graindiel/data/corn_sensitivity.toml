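# Spherical reference kernel for surface-area / shape / configuration sweeps.
[grain]
name = "corn (sensitivity)"

[shape]
aspect = 1.0
k = 3.0

[densities]
units = "kg/m3"
rho_s = 1500.0
rho_b = 750.0
rho_w = 1000.0

[dielectric]
eps_s = 2.5
eps_a = 1.0

[water]
A_s = 200.0
T = 298.0
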