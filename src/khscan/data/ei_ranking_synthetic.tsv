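# SYNTHETIC exchangeability ranking (stand-in for a measured evolutionary index).
# The 75 elementary amino-acid change classes of the standard genetic code,
# ordered by increasing Grantham (1974) physicochemical distance
# (most similar pair = rank 1). Generated by khscan.grantham.grantham_ranking().
aa1	aa2	rank
I	L	1
I	M	2
L	M	3
F	I	4
M	V	5
F	Y	6
F	L	7
D	N	8
H	Q	9
K	R	10
A	P	11
H	R	12
E	Q	13
I	V	14
L	V	15
P	T	16
Q	R	17
D	E	18
N	S	19
F	V	20
K	Q	21
G	S	22
E	K	23
S	T	24
A	T	25
A	G	26
L	W	27
A	V	28
N	T	29
H	N	30
R	T	31
P	S	32
P	Q	33
H	P	34
K	T	35
M	T	36
D	H	37
H	Y	38
I	T	39
M	R	40
D	G	41
K	N	42
K	M	43
I	R	44
L	P	45
E	G	46
H	L	47
A	S	48
R	W	49
I	K	50
L	R	51
P	R	52
A	E	53
G	V	54
R	S	55
C	S	56
L	Q	57
E	V	58
G	R	59
A	D	60
I	S	61
N	Y	62
S	Y	63
L	S	64
I	N	65
D	V	66
F	S	67
C	G	68
D	Y	69
S	W	70
C	R	71
G	W	72
C	Y	73
C	F	74
C	W	75
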