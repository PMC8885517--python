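# Monoisotopic residue formulas (amino acid minus water) for the 20 standard
# residues. The nitrogen count doubles as the 15N label multiplicity: every
# residue nitrogen is metabolically labeled.
# columns: code, name, C, H, N, O, S
code	name	C	H	N	O	S
G	Glycine	2	3	1	1	0
A	Alanine	3	5	1	1	0
S	Serine	3	5	1	2	0
P	Proline	5	7	1	1	0
V	Valine	5	9	1	1	0
T	Threonine	4	7	1	2	0
C	Cysteine	3	5	1	1	1
L	Leucine	6	11	1	1	0
I	Isoleucine	6	11	1	1	0
N	Asparagine	4	6	2	2	0
D	Aspartate	4	5	1	3	0
Q	Glutamine	5	8	2	2	0
K	Lysine	6	12	2	1	0
E	Glutamate	5	7	1	3	0
M	Methionine	5	9	1	1	1
H	Histidine	6	7	3	1	0
F	Phenylalanine	9	9	1	1	0
R	Arginine	6	12	4	1	0
Y	Tyrosine	9	9	1	2	0
W	Tryptophan	11	10	2	1	0
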