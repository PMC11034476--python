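residue	v1	v2	v3	v4	v5	v6	v7	v8
A	0.65	-0.35	1.8	0.83	-1.74	-2.23	0.38	0.81
R	-2.12	1.49	0.82	0.27	-0.02	-0.67	-0.63	3.19
N	-1.09	1.29	0.49	-3.07	-0.46	2.82	-0.22	-3.0
D	0.17	-1.41	-0.03	-0.85	0.12	-1.08	-0.68	0.85
C	-0.5	3.95	-2.9	-1.22	-1.18	-1.39	-0.79	-1.54
Q	1.89	-0.11	1.18	0.45	-1.47	-0.5	1.7	-1.43
E	-1.47	-0.34	4.51	0.55	1.3	-3.36	1.96	1.14
G	-1.24	-2.21	-2.15	0.43	3.57	-0.81	-1.14	1.64
H	1.91	1.64	-0.79	0.17	-0.19	-0.75	0.6	-0.23
I	1.68	-1.81	-1.24	-1.63	-2.17	-0.88	-2.99	0.48
L	-0.29	-0.91	0.87	1.99	0.89	2.57	2.03	-2.31
K	-0.32	-1.64	0.83	-3.42	0.65	1.17	1.14	0.19
M	-1.76	1.28	-2.4	2.55	0.77	2.03	2.53	2.22
F	0.68	0.67	-1.73	2.18	-0.64	1.32	-2.68	-0.84
P	0.74	1.48	1.08	1.83	0.63	-1.17	-2.26	-1.72
S	-1.78	-2.07	1.53	-2.01	1.74	-0.37	2.12	-0.61
T	0.79	0.46	-2.1	0.12	-2.87	1.81	-2.15	0.31
W	1.93	-2.68	-1.96	0.48	0.07	-1.38	-0.57	-0.47
Y	0.62	-0.26	1.07	-0.46	-0.5	2.03	0.85	2.56
V	-0.55	1.53	1.16	0.82	1.58	0.82	0.86	-1.33
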