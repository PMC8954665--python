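# Monolayer (single-molecular-layer) bound-water contents, dry basis,
# for proteins, starches and flours, with the specific surface areas
# inferred from them via the monolayer packing relation.

[[measurements]]
material = "BSA"
M_db = 0.25
A_s = 633

[[measurements]]
material = "34 protein avg."
M_db = 0.28
A_s = 709

[[measurements]]
material = "beta-casein"
M_db = 0.24
A_s = 607

[[measurements]]
material = "myoglobin"
M_db = 0.22
A_s = 557

[[measurements]]
material = "wheat starch"
M_db = 0.17
A_s = 430

[[measurements]]
material = "corn starch (TSDC)"
M_db = 0.15
A_s = 380

[[measurements]]
material = "corn starch (NMR)"
M_db = 0.19
A_s = 481

[[measurements]]
material = "maize"
M_db = 0.08
A_s = 202

[[measurements]]
material = "bean flour"
M_db = 0.17
A_s = 430

[[measurements]]
material = "soy flour"
M_db = 0.39
A_s = 987

[[measurements]]
material = "wheat flour"
M_db = 0.11
A_s = 278
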