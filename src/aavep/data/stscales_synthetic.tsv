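residue	st1	st2	st3	st4	st5	st6	st7	st8
A	2.77	0.87	0.4	-1.03	1.39	1.3	0.22	3.59
R	-0.02	1.49	1.49	-0.06	-2.7	0.88	-1.71	1.34
N	-0.44	-2.43	-1.75	-1.24	-0.19	-1.68	2.47	-0.18
D	0.1	-0.54	-0.84	-0.02	1.04	-2.57	0.93	-1.95
C	0.93	0.12	0.88	1.95	1.3	-0.5	0.36	0.32
Q	0.6	1.42	1.24	1.42	0.05	0.25	-1.29	1.67
E	1.39	-0.32	0.18	2.22	-1.5	0.43	1.62	-0.34
G	2.27	1.64	-0.88	2.65	1.36	1.68	-1.84	0.98
H	-1.36	1.82	-0.19	1.99	1.41	1.45	-1.59	-0.29
I	1.51	-1.03	2.99	0.6	-1.25	0.53	0.18	0.16
L	-1.49	0.87	-0.88	1.04	-0.19	-1.59	-1.09	-2.51
K	-1.11	1.16	-0.9	-1.44	-0.7	0.18	1.48	-1.26
M	-0.39	1.45	1.79	1.76	1.26	-1.42	-0.83	-0.87
F	1.25	-2.08	-1.32	-3.93	-0.42	1.77	-1.6	1.94
P	-1.23	-1.45	0.73	-2.81	2.27	-0.42	-1.07	0.12
S	0.82	-1.21	1.05	-2.42	-2.3	-0.64	-0.09	0.54
T	-1.73	-2.99	-1.11	0.82	-0.42	0.57	-0.95	-1.34
W	-1.74	0.25	-2.16	0.56	-1.06	1.01	0.31	-2.06
Y	-0.65	0.23	-2.42	-2.91	0.55	0.4	4.41	-1.13
V	-1.4	0.71	1.68	0.88	0.04	-1.62	0.14	1.28
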