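residue	b1	b2	b3	b4	b5	b6	b7	b8	b9	b10
A	0.52	-0.77	-2.11	-0.97	-2.03	0.66	-1.3	-0.05	0.88	-1.3
R	0.47	1.34	-0.55	-1.46	-2.39	0.41	0.2	-1.63	3.57	1.54
N	0.42	1.85	-0.82	0.68	1.07	0.07	1.51	-3.26	-0.15	-0.58
D	0.46	0.58	-0.06	0.53	0.78	-1.72	0.35	3.05	1.0	-1.86
C	0.57	-1.38	0.57	-1.27	0.59	-1.17	2.98	2.96	-0.72	-0.28
Q	-0.61	-0.77	0.74	0.33	1.01	-2.16	0.79	-0.21	-0.35	-0.45
E	1.04	-0.34	-1.23	0.33	1.0	0.58	-1.27	0.56	-0.57	-1.73
G	0.4	-0.8	3.33	0.5	0.02	1.07	-2.54	-1.56	-0.94	0.81
H	-0.91	-2.73	0.57	1.27	0.14	-1.52	1.54	3.23	0.71	2.85
I	-1.83	-0.02	-1.24	2.36	1.85	0.51	0.19	0.3	-0.11	-1.21
L	-0.9	-0.51	0.85	-2.39	-1.21	0.05	-0.2	-2.26	-0.99	3.17
K	2.29	0.11	-0.53	1.31	-0.01	2.68	-1.23	1.75	1.24	-0.39
M	1.96	1.81	1.03	-1.12	-0.53	0.57	2.25	-0.8	-0.69	-0.98
F	-0.52	-0.73	0.43	1.53	-2.13	-0.35	0.4	0.37	-1.39	0.47
P	1.19	1.35	2.19	-0.5	2.2	-0.11	-1.86	-1.57	-1.56	-2.03
S	0.22	-1.92	-0.11	0.59	-1.0	0.11	0.42	-1.26	0.1	0.0
T	-1.77	-0.99	-0.6	-0.5	0.84	1.34	1.87	-1.04	1.04	0.55
W	-1.6	1.55	1.14	-3.41	-1.37	-1.46	-3.66	0.03	-1.15	0.74
Y	1.46	-0.52	-3.02	0.25	-0.04	0.0	-1.16	1.37	-0.05	-0.11
V	-2.86	2.89	-0.65	2.03	1.25	0.39	0.8	0.03	0.21	0.72
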