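group,genotype,yield_liter_per_bag,productivity_bag_per_ha
I,Emcapa 143,312.26,94.65
I,Tardio V,329.95,69.84
I,Imbigudinho,324.82,79.67
I,Z29,366.61,70.15
I,18,422.67,49.30
I,Clementino,355.48,97.86
I,Bicudo,366.21,93.09
I,Z37,363.78,86.84
I,Ouro Negro,346.39,75.24
I,CH1,359.87,81.40
I,Beira rio 8,439.72,61.81
I,Z35,402.23,72.48
I,Bamburral,357.23,86.60
I,LB1,312.21,118.08
I,Verdim R,398.32,82.35
I,Z21,294.01,102.49
II,Tardio C,345.15,74.73
II,B01,418.21,43.11
II,Z39,339.92,95.48
II,Ouro Negro 2,316.46,74.70
II,A1,365.44,108.19
II,Alecrim,341.46,54.37
II,Z36,316.62,91.45
II,Verdim D,336.65,90.43
II,Ouro Negro 1,359.87,72.23
II,Clone 1,,
II,Valcir P,341.11,87.93
II,Graudão HP,317.59,86.13
II,Z38,372.53,74.94
III,AP,313.53,86.28
III,122,330.03,81.07
III,P2,316.7,92.32
III,P1,332.5,93.47
III,700,303.23,89.19
III,Clone 2,,
III,Pirata,379.63,76.22
III,L80,364.68,105.53
IV,Z18,330.2,80.05
IV,Z40,356.18,74.55
IV,Emcapa 153,322.45,85.52
IV,Peneirão,326.6,99.22
IV,AT,303.49,128.93
IV,Emcapa 02,323.18,97.10
V,Sementes,348.06,70.32
VI,Arabica,,
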