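sample_number,name
1,AP
2,Ouro negro 2
3,18
4,Ouro negro 1
5,Graudão HP
6,Peneirão
7,Ouro Negro
8,Z18
9,Clementino
10,Beira Rio 8
11,Verdim D
12,Z39
13,Bamburral
14,P2
15,Imbigudinho
16,AT
17,Emcapa 153
18,Bicudo
19,Alecrim
20,Z38
21,122
22,Sementes
23,Valcir P
24,Clone 1
25,Z40
26,CH1
27,Emcapa 143
28,Verdim R
29,Tardio C
30,Clone 2
31,700
32,Z29
33,Emcapa 02
34,Pirata
35,A1
36,Z36
37,Z37
38,B01
39,Tardio V
40,Z21
41,Z35
42,LB1
43,L80
44,P1
45,Arabica
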