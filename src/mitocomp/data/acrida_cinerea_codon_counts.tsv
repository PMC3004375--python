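# Codon usage of the 13 protein-coding genes of the Acrida cinerea mitogenome
# (GenBank GU344100), invertebrate mitochondrial code; 3720 codons, stops excluded.
codon	aa	n
UUU	F	296
UUC	F	57
UUA	L	356
UUG	L	36
CUU	L	44
CUC	L	3
CUA	L	62
CUG	L	2
AUU	I	364
AUC	I	34
AUA	M	256
AUG	M	37
GUU	V	90
GUC	V	2
GUA	V	71
GUG	V	4
UCU	S	109
UCC	S	9
UCA	S	129
UCG	S	3
CCU	P	53
CCC	P	4
CCA	P	73
CCG	P	5
ACU	T	53
ACC	T	15
ACA	T	131
ACG	T	4
GCU	A	60
GCC	A	5
GCA	A	84
GCG	A	2
UAU	Y	147
UAC	Y	25
UAA	*	0
UAG	*	0
CAU	H	52
CAC	H	14
CAA	Q	53
CAG	Q	11
AAU	N	160
AAC	N	17
AAA	K	79
AAG	K	23
GAU	D	64
GAC	D	10
GAA	E	71
GAG	E	10
UGU	C	37
UGC	C	6
UGA	W	87
UGG	W	11
CGU	R	22
CGC	R	1
CGA	R	35
CGG	R	0
AGU	S	31
AGC	S	1
AGA	S	79
AGG	S	6
GGU	G	91
GGC	G	5
GGA	G	114
GGG	G	5
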