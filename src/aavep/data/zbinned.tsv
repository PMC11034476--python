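residue	z1	z2	z3
A	0	-1	0
R	1	1	-1
N	1	1	1
D	1	0	1
C	0	0	1
Q	0	0	-1
E	1	0	0
G	1	-1	0
H	1	1	1
I	-1	-1	-1
L	-1	-1	-1
K	1	1	-1
M	-1	0	0
F	-1	1	0
P	0	0	1
S	0	-1	1
T	0	-1	-1
W	-1	1	1
Y	-1	1	0
V	-1	-1	-1
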