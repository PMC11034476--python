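residue	pc1	pc2	pc3
A	0.83	1.78	-3.0
R	-0.95	-0.89	1.42
N	0.94	1.41	-0.29
D	-0.94	0.64	-0.27
C	-1.27	0.64	-0.87
Q	-2.71	-2.39	0.92
E	-0.26	-0.08	0.99
G	3.26	0.16	2.99
H	1.57	1.51	0.0
I	1.52	-0.16	-1.18
L	-0.2	-0.07	-0.27
K	1.36	-3.95	-1.61
M	-1.61	-1.54	0.56
F	0.41	-0.65	0.92
P	-0.04	0.05	2.05
S	-1.47	-0.14	-0.28
T	-0.5	3.58	-0.92
W	-1.37	-1.3	-0.76
Y	2.17	1.2	-0.4
V	-0.78	0.12	-0.09
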