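residue	pc1	pc2	pc3	pc4	pc5	pc6	pc7	pc8
A	-1.95	0.46	2.52	-1.26	3.27	-0.19	-1.63	0.07
R	-0.8	0.5	1.53	-0.45	-1.56	0.02	-1.09	-1.22
N	1.25	2.43	-1.46	1.21	-1.75	0.67	2.13	-0.25
D	-0.68	0.66	-0.56	-1.97	1.31	0.58	0.61	-1.85
C	1.63	-1.09	-3.16	1.22	-1.52	0.32	-3.52	-0.68
Q	-1.7	0.97	-0.37	-0.45	-2.08	1.03	1.49	0.55
E	0.73	-0.0	0.83	0.69	0.01	1.31	0.02	-0.96
G	1.33	1.28	-0.19	-0.84	0.09	-2.61	0.96	0.97
H	2.32	-0.43	-2.12	1.15	0.85	2.88	-0.15	-0.64
I	-3.49	-1.4	-1.57	-0.79	2.2	3.05	2.95	-0.01
L	2.57	-0.44	-0.19	-3.5	-1.48	-1.86	0.77	2.11
K	0.37	3.18	0.7	1.81	-0.03	-0.93	-2.92	0.06
M	1.24	1.72	1.43	1.41	-2.45	-0.11	-0.56	2.5
F	-0.52	-2.12	0.47	0.2	-1.31	-1.53	-1.39	1.13
P	-0.09	-0.84	0.72	2.8	2.59	0.64	-3.29	-0.95
S	-0.99	-0.31	0.9	-1.31	0.61	0.08	0.3	0.23
T	-1.12	0.27	-1.36	-0.56	2.56	-0.97	0.99	1.01
W	-0.21	0.03	0.11	-0.17	0.69	-1.43	1.04	-1.18
Y	-3.35	-1.5	1.8	1.5	-0.18	0.98	1.08	0.26
V	3.42	-3.36	-0.1	-0.77	-1.82	-1.85	2.16	-1.2
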