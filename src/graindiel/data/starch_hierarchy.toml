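# Structural hierarchy of corn starch, outer to inner, with idealized
# geometry and characteristic radius (m). Constituent solid density in
# g/cm3. Cylinders use the cylinder (cross-section) radius.
constituent_density_g_cm3 = 1.52

[[levels]]
name = "starch grain"
geometry = "sphere"
radius_m = 1.0e-6

[[levels]]
name = "large blocklets"
geometry = "sphere"
radius_m = 2.5e-8

[[levels]]
name = "small blocklets"
geometry = "sphere"
radius_m = 1.0e-8

[[levels]]
name = "amylopectin cluster"
geometry = "cylinder"
radius_m = 5.0e-9

[[levels]]
name = "amylopectin/amylose unit cell"
geometry = "cylinder"
radius_m = 8.0e-10
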