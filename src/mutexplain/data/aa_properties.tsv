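# One row per standard amino acid.
# columns: code	name	hydrophobicity	volume	charge	flags
# hydrophobicity: Kyte-Doolittle scale (dimensionless)
# volume: Zamyatnin residue volumes (cubic Angstrom)
# charge: formal side-chain charge at pH 7 (His treated as neutral)
# flags: comma-separated subset of
#   HELIX_BREAKER,FLEXIBLE,DISULFIDE_CAPABLE,PHOSPHO_ACCEPTOR,AROMATIC or '.'
A	alanine	1.8	88.6	0	.
R	arginine	-4.5	173.4	1	.
N	asparagine	-3.5	114.1	0	.
D	aspartate	-3.5	111.1	-1	.
C	cysteine	2.5	108.5	0	DISULFIDE_CAPABLE
Q	glutamine	-3.5	143.8	0	.
E	glutamate	-3.5	138.4	-1	.
G	glycine	-0.4	60.1	0	HELIX_BREAKER,FLEXIBLE
H	histidine	-3.2	153.2	0	AROMATIC
I	isoleucine	4.5	166.7	0	.
L	leucine	3.8	166.7	0	.
K	lysine	-3.9	168.6	1	.
M	methionine	1.9	162.9	0	.
F	phenylalanine	2.8	189.9	0	AROMATIC
P	proline	-1.6	112.7	0	HELIX_BREAKER
S	serine	-0.8	89.0	0	PHOSPHO_ACCEPTOR
T	threonine	-0.7	116.1	0	PHOSPHO_ACCEPTOR
W	tryptophan	-0.9	227.8	0	AROMATIC
Y	tyrosine	-1.3	193.6	0	PHOSPHO_ACCEPTOR,AROMATIC
V	valine	4.2	140.0	0	.
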