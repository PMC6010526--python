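residue	v1	v2	v3
A	1.00	0.007187	0.31
R	6.13	0.043587	-1.01
N	2.95	0.005392	-0.60
D	2.78	-0.023820	-0.77
C	2.43	-0.036610	1.54
Q	3.95	0.049211	-0.22
E	3.78	0.006802	-0.64
G	0.00	0.179052	0.00
H	4.66	-0.010690	0.13
I	4.00	0.021631	1.80
L	4.00	0.051672	1.70
K	4.77	0.017708	-0.99
M	4.43	0.002683	1.23
F	5.89	0.037552	1.79
P	2.72	0.239531	0.72
S	1.60	0.004627	-0.04
T	2.60	0.003352	0.26
W	8.08	0.037977	2.25
Y	6.47	0.023599	0.96
V	3.00	0.057004	1.22
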