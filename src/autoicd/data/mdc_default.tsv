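prefix_start	prefix_end	mdc
B20	B24	25
A00	B99	18
C00	D48	17
D50	D89	16
E00	E90	10
F10	F19	20
F00	F99	19
G00	G99	1
H00	H59	2
H60	H95	3
I00	I99	5
J00	J99	4
K70	K87	7
K00	K93	6
L00	L99	9
M00	M99	8
N40	N53	12
N60	N98	13
N00	N99	11
O00	O99	14
P00	P96	15
R00	R99	23
T20	T32	22
S00	T98	21
Z00	Z99	23
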