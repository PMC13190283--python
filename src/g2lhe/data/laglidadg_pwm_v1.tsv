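# LAGLIDADG position-weight matrix, version 1
# log2 odds vs uniform background (1/20); columns 1-10, rows = residues
# column 8 is the catalytic acidic position
res	c1	c2	c3	c4	c5	c6	c7	c8	c9	c10
A	0.0000	2.5850	2.0000	-2.3219	-2.0000	-2.0000	2.5850	-3.0875	2.0000	1.0000
R	-3.8074	-2.3219	-2.0875	-2.3219	-2.0000	-2.0000	-1.4150	-3.0875	-2.5025	-1.5850
N	-3.8074	-2.3219	-2.0875	-2.3219	-2.0000	1.5850	-1.4150	0.0000	-2.5025	-1.5850
D	-3.8074	-2.3219	-2.0875	-2.3219	-2.0000	3.0000	-1.4150	3.4594	-2.5025	-1.5850
C	-3.8074	1.0000	-2.0875	-2.3219	-2.0000	-2.0000	0.0000	-3.0875	-2.5025	-1.5850
Q	-3.8074	-2.3219	-2.0875	-2.3219	-2.0000	-2.0000	-1.4150	-3.0875	-2.5025	-1.5850
E	-3.8074	-2.3219	-2.0875	-2.3219	-2.0000	2.0000	-1.4150	2.5850	-2.5025	-1.5850
G	-3.8074	2.0000	3.3219	-2.3219	-2.0000	-2.0000	2.0000	-3.0875	3.4594	0.0000
H	-3.8074	-2.3219	-2.0875	-2.3219	-2.0000	-2.0000	-1.4150	-3.0875	-2.5025	-1.5850
I	2.0000	-2.3219	-2.0875	2.0000	2.5850	-2.0000	-1.4150	-3.0875	-2.5025	1.5850
L	2.8074	-2.3219	-2.0875	2.8074	2.3219	-2.0000	-1.4150	-3.0875	-2.5025	2.0000
K	-3.8074	-2.3219	-2.0875	-2.3219	-2.0000	-2.0000	-1.4150	-3.0875	-2.5025	-1.5850
M	1.0000	-2.3219	-2.0875	0.0000	0.0000	-2.0000	-1.4150	-3.0875	-2.5025	0.0000
F	1.0000	-2.3219	-2.0875	1.0000	-2.0000	-2.0000	-1.4150	-3.0875	-2.5025	-1.5850
P	-3.8074	-2.3219	-2.0875	-2.3219	-2.0000	-2.0000	-1.4150	-3.0875	-2.5025	-1.5850
S	-3.8074	1.5850	1.0000	-2.3219	-2.0000	0.0000	1.5850	-3.0875	1.0000	0.0000
T	-3.8074	1.0000	-2.0875	-2.3219	-2.0000	-2.0000	-1.4150	-3.0875	-2.5025	0.0000
W	-3.8074	-2.3219	-2.0875	-2.3219	-2.0000	-2.0000	-1.4150	-3.0875	-2.5025	-1.5850
Y	-3.8074	-2.3219	-2.0875	-2.3219	-2.0000	-2.0000	-1.4150	-3.0875	-2.5025	-1.5850
V	1.5850	-2.3219	-2.0875	1.5850	2.0000	-2.0000	-1.4150	-3.0875	-2.5025	1.5850
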