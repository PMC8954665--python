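# Measured physical properties of packed cereal grains at 12-16% wb
# moisture (soybean at 14%). Densities in g/cm3.

[corn]
rho_b = 0.745
phi_b = 0.40
rho_k = 1.24
rho_s = 1.45
aspect = 1.35

[rice]
rho_b = 0.590
phi_b = 0.48
rho_k = 1.13
rho_s = 1.43
aspect = 2.65

[wheat]
rho_b = 0.805
phi_b = 0.41
rho_k = 1.36
rho_s = 1.47
aspect = 1.9

[soybean]
rho_b = 0.721
phi_b = 0.382
rho_k = 1.17
rho_s = 1.34
aspect = 0.81
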