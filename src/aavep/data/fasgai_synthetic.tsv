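residue	f1	f2	f3	f4	f5	f6
A	0.14	-1.6	0.73	1.01	-1.44	1.78
R	-0.17	1.56	1.14	2.0	-0.37	1.44
N	-1.22	-2.06	0.07	-0.57	-0.17	-0.51
D	0.25	1.65	-0.27	0.22	1.38	-0.04
C	-0.06	2.5	-1.87	0.04	-0.16	-0.44
Q	0.61	-0.08	-1.39	1.56	1.07	-0.12
E	0.95	-0.82	-0.76	-0.34	0.51	0.56
G	-1.14	1.51	1.36	-0.7	0.65	-0.08
H	2.29	-1.4	0.4	0.77	2.2	-0.65
I	-1.03	1.23	1.84	-0.88	-0.49	-2.19
L	0.63	-0.52	2.37	-1.01	-1.33	3.42
K	-0.66	-0.09	-1.49	-0.73	0.87	0.98
M	-0.39	-1.0	-0.26	-1.66	-1.02	0.07
F	1.5	0.11	-0.75	-1.0	-0.84	-1.25
P	-0.33	0.1	-1.85	-3.81	0.55	1.23
S	2.92	1.61	-2.24	2.63	1.18	0.9
T	-2.54	-0.05	-0.7	-0.41	1.14	-1.13
W	-2.35	-1.68	2.85	0.71	-2.49	-0.96
Y	-1.16	1.04	-0.5	0.6	-0.54	-3.02
V	1.83	-1.97	1.26	1.56	-0.66	-0.01
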