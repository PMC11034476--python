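residue	w1	w2	w3
A	0.02	0.45	-1.68
R	-0.52	-1.52	1.09
N	-0.42	2.72	-1.33
D	-1.06	-1.04	-2.24
C	1.53	0.21	-1.91
Q	-1.54	-0.25	2.9
E	2.73	-0.18	2.09
G	-2.08	1.36	0.18
H	-0.28	-0.48	-0.18
I	2.22	-1.26	0.09
L	1.67	1.69	-0.84
K	1.56	-0.07	-3.76
M	0.87	1.42	-0.17
F	-0.37	1.12	1.0
P	0.33	0.33	2.84
S	-1.23	-3.18	-0.01
T	1.27	0.43	-1.86
W	-3.46	0.7	5.98
Y	-0.72	-1.32	-1.13
V	-0.58	-1.2	-1.04
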