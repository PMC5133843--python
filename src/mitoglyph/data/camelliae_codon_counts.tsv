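# Codon counts for the 13 protein-coding genes of the Aleurocanthus
# camelliae mitogenome, as published (RNA spelling; stops included).
codon	n
UAA	8
UAG	2
GCA	62
GCC	23
GCG	14
GCU	60
UGC	17
UGU	29
GAC	22
GAU	41
GAA	57
GAG	26
UUC	46
UUU	304
GGA	62
GGC	20
GGG	55
GGU	42
CAC	22
CAU	29
AUC	48
AUU	291
AAA	79
AAG	43
CUA	91
CUC	16
CUG	42
CUU	87
UUA	178
UUG	90
AUA	225
AUG	67
AAC	48
AAU	104
CCA	26
CCC	18
CCG	13
CCU	37
CAA	29
CAG	22
CGA	18
CGC	5
CGG	12
CGU	10
AGA	76
AGC	23
AGG	22
AGU	55
UCA	83
UCC	18
UCG	17
UCU	80
ACA	76
ACC	19
ACG	6
ACU	87
GUA	85
GUC	21
GUG	49
GUU	106
UGA	68
UGG	32
UAC	48
UAU	99
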