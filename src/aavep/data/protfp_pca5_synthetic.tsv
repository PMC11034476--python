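residue	pc1	pc2	pc3	pc4	pc5
A	-0.64	-1.19	0.67	-1.38	0.66
R	0.7	-1.46	-0.1	2.31	-0.29
N	-0.83	-0.79	2.81	0.13	-0.45
D	-0.09	4.01	-3.07	-0.06	0.49
C	-1.48	-0.97	1.5	0.44	3.79
Q	3.1	-2.06	-2.36	0.77	0.16
E	-1.98	0.67	-0.39	-2.37	0.04
G	0.71	-0.89	0.69	0.2	0.15
H	2.37	2.6	0.23	-0.29	0.89
I	-2.11	-0.52	-0.61	-0.02	-0.53
L	-1.95	0.61	-1.49	-0.1	0.71
K	0.7	2.18	0.47	0.87	-2.37
M	0.02	1.37	0.59	0.06	1.48
F	-0.33	0.93	0.67	-1.7	1.06
P	2.24	0.59	0.12	0.11	-1.1
S	1.82	-1.1	-0.11	-2.79	-0.25
T	0.6	-0.9	-1.8	-0.3	0.12
W	0.01	-0.83	0.06	0.25	-0.88
Y	-1.89	-1.65	1.4	0.58	-0.27
V	-1.06	-0.66	0.75	3.23	-3.43
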