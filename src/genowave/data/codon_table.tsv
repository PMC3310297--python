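amino_acid	name	codons
M	Methionine	ATG
E	Glutamic acid	GAA,GAG
Q	Glutamine	CAA,CAG
D	Aspartic acid	GAT,GAC
R	Arginine	CGT,CGC,CGA,CGG,AGA,AGG
T	Threonine	ACT,ACC,ACA,ACG
N	Asparagine	AAT,AAC
H	Histidine	CAT,CAC
V	Valine	GTT,GTC,GTA,GTG
G	Glycine	GGT,GGC,GGA,GGG
L	Leucine	TTA,TTG,CTT,CTC,CTA,CTG
S	Serine	TCT,TCC,TCA,TCG,AGT,AGC
P	Proline	CCT,CCC,CCA,CCG
F	Phenylalanine	TTT,TTC
I	Isoleucine	ATT,ATC,ATA
C	Cysteine	TGT,TGC
A	Alanine	GCT,GCC,GCA,GCG
K	Lysine	AAA,AAG
Y	Tyrosine	TAT,TAC
W	Tryptophan	TGG
*	Stop	TAA,TAG,TGA
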