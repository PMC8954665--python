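# Major-constituent mass fractions (percent of kernel) and reference
# constituent solid densities (g/cm3). Fractions omit minor
# constituents and do not sum to 100; normalize before use.

[densities]
starch = 1.5
protein = 1.4
fat = 0.925
fiber = 1.44

[corn]
starch = 63.6
protein = 9.8
fat = 4.9
fiber = 2.0

[rice]
starch = 64.3
protein = 7.3
fat = 2.2
fiber = 0.8

[wheat]
starch = 69.7
protein = 10.6
fat = 1.9
fiber = 1.0

[soybean]
starch = 31.6
protein = 34.3
fat = 18.7
fiber = 3.8

[lentil]
starch = 61.2
protein = 24.7
fat = 1.0
fiber = 4.1
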