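residue	f1	f2	f3	f4	f5	f6	f7	f8
A	-0.76	-0.34	-0.24	0.24	-3.18	0.87	1.03	0.62
R	-2.39	-0.93	-1.66	4.15	1.95	2.53	-3.42	-0.66
N	2.18	-0.58	0.41	0.14	-1.06	1.06	-0.08	0.13
D	0.92	0.5	-0.78	2.82	1.93	1.15	-0.62	2.18
C	-0.8	1.28	-0.9	0.19	0.03	-0.44	1.94	-0.17
Q	-1.49	-0.5	3.54	-1.01	1.22	-2.55	-0.47	0.03
E	0.63	2.34	1.77	-1.12	0.15	0.15	-0.45	-2.46
G	-0.41	-0.54	2.13	-0.02	1.03	2.89	1.49	-0.78
H	0.5	2.11	0.52	-1.54	-0.23	0.62	0.33	-1.37
I	1.74	-2.34	-0.91	-0.03	-3.42	-0.68	-0.48	4.07
L	0.7	0.61	1.59	1.1	1.8	-1.61	1.7	1.91
K	-0.19	-1.29	-1.34	-0.68	-2.19	0.11	-1.6	-1.13
M	-1.39	1.05	-0.35	-1.91	0.78	-0.96	2.2	-0.57
F	0.97	2.28	0.03	1.61	0.26	-2.18	0.72	-0.63
P	-0.61	0.48	-0.36	-0.51	1.89	-0.45	-1.83	3.53
S	1.82	-0.1	0.28	-2.31	0.41	1.23	-0.27	-0.56
T	-1.44	-1.15	-2.38	-2.03	0.79	0.57	1.08	-2.11
W	-0.63	-4.13	0.41	1.36	-0.48	-2.63	-0.02	-1.9
Y	-0.3	0.6	-2.02	-0.75	-0.0	-0.28	-0.6	-0.29
V	0.92	0.65	0.32	0.29	-1.62	0.6	-0.62	0.11
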