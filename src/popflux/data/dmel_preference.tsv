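codon	amino_acid	status
AAA	K	unpreferred
AAC	N	preferred
AAG	K	preferred
AAT	N	unpreferred
ACA	T	unpreferred
ACC	T	preferred
ACG	T	unpreferred
ACT	T	unpreferred
AGA	R	unpreferred
AGC	S	preferred
AGG	R	unpreferred
AGT	S	unpreferred
ATA	I	unpreferred
ATC	I	preferred
ATG	M	not_applicable
ATT	I	unpreferred
CAA	Q	unpreferred
CAC	H	preferred
CAG	Q	preferred
CAT	H	unpreferred
CCA	P	unpreferred
CCC	P	preferred
CCG	P	unpreferred
CCT	P	unpreferred
CGA	R	unpreferred
CGC	R	preferred
CGG	R	unpreferred
CGT	R	unpreferred
CTA	L	unpreferred
CTC	L	unpreferred
CTG	L	preferred
CTT	L	unpreferred
GAA	E	unpreferred
GAC	D	preferred
GAG	E	preferred
GAT	D	unpreferred
GCA	A	unpreferred
GCC	A	preferred
GCG	A	unpreferred
GCT	A	unpreferred
GGA	G	unpreferred
GGC	G	preferred
GGG	G	unpreferred
GGT	G	unpreferred
GTA	V	unpreferred
GTC	V	unpreferred
GTG	V	preferred
GTT	V	unpreferred
TAC	Y	preferred
TAT	Y	unpreferred
TCA	S	unpreferred
TCC	S	unpreferred
TCG	S	unpreferred
TCT	S	unpreferred
TGC	C	preferred
TGG	W	not_applicable
TGT	C	unpreferred
TTA	L	unpreferred
TTC	F	preferred
TTG	L	unpreferred
TTT	F	unpreferred
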