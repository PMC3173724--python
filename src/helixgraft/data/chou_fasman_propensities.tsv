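# Chou-Fasman conformational propensities (x100)
# residue	P_helix	P_sheet	P_turn
A	142	83	66
R	98	93	95
N	67	89	156
D	101	54	146
C	70	119	119
E	151	37	74
Q	111	110	98
G	57	75	156
H	100	87	95
I	108	160	47
L	121	130	59
K	114	74	101
M	145	105	60
F	113	138	60
P	57	55	152
S	77	75	143
T	83	119	96
W	108	137	96
Y	69	147	114
V	106	170	50
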