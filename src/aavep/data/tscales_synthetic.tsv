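residue	t1	t2	t3	t4	t5
A	0.43	-1.37	0.58	-1.73	-0.51
R	-0.68	0.16	0.4	0.3	-0.49
N	-0.87	0.08	-1.19	-1.66	-1.65
D	1.72	-2.03	0.19	-0.82	0.43
C	-0.21	-0.79	-0.92	-0.34	-1.6
Q	-0.7	-0.87	0.16	0.19	-0.55
E	-0.01	3.62	2.31	0.68	0.79
G	0.94	0.6	2.54	0.24	-0.58
H	-1.26	-0.94	-1.33	0.81	3.11
I	1.53	3.55	-1.5	-1.0	0.34
L	-0.44	-2.36	0.73	0.54	2.6
K	-1.06	-1.12	0.27	1.27	-0.32
M	-1.5	-0.68	-1.67	-0.93	-0.21
F	-0.22	-2.58	-0.52	0.14	-1.21
P	-1.18	0.6	0.2	1.98	1.14
S	-1.35	0.52	-1.97	0.33	-1.97
T	-1.62	1.13	1.22	-0.22	-1.34
W	2.0	1.38	0.32	0.15	0.08
Y	1.58	1.64	0.31	-0.99	-1.02
V	2.82	-0.54	-0.04	1.07	2.97
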