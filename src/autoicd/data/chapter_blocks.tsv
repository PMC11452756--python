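block_start	block_end	chapter
A00	B99	I
C00	D48	II
D50	D89	III
E00	E90	IV
F00	F99	V
G00	G99	VI
H00	H59	VII
H60	H95	VIII
I00	I99	IX
J00	J99	X
K00	K93	XI
L00	L99	XII
M00	M99	XIII
N00	N99	XIV
O00	O99	XV
P00	P96	XVI
Q00	Q99	XVII
R00	R99	XVIII
S00	T98	XIX
V01	Y98	XX
Z00	Z99	XXI
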