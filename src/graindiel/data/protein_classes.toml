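# Seed-protein class composition (percent of total protein) per cereal,
# reference molecular weights (g/mol) per class, and the kernel protein
# content (percent of kernel dry mass; ranged values already averaged).

[molecular_weights]
albumin = 12000.0
globulin = 320000.0
prolamin = 21000.0
glutelin = 1.0e6

[cereals.barley]
albumin = 13.0
globulin = 12.0
prolamin = 52.0
glutelin = 23.0
kernel_protein_percent = 10.9

[cereals.maize]
albumin = 4.0
globulin = 2.0
prolamin = 55.0
glutelin = 39.0
kernel_protein_percent = 10.0

[cereals.millet]
albumin = 13.2
globulin = 9.4
prolamin = 40.0
glutelin = 28.0
kernel_protein_percent = 16.0

[cereals.oat]
albumin = 1.0
globulin = 78.0
prolamin = 16.0
glutelin = 5.0
kernel_protein_percent = 11.0

[cereals.rice]
albumin = 5.0
globulin = 10.0
prolamin = 5.0
glutelin = 80.0
kernel_protein_percent = 9.0

[cereals.rye]
albumin = 10.0
globulin = 10.0
prolamin = 40.0
glutelin = 40.0
kernel_protein_percent = 11.5

[cereals.sorghum]
albumin = 8.0
globulin = 8.0
prolamin = 52.0
glutelin = 32.0
kernel_protein_percent = 11.0

[cereals.triticale]
albumin = 26.4
globulin = 6.5
prolamin = 24.4
glutelin = 36.3
kernel_protein_percent = 15.0

[cereals.wheat]
albumin = 5.0
globulin = 10.0
prolamin = 69.0
glutelin = 16.0
kernel_protein_percent = 12.2
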