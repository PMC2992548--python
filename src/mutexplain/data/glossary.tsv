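# Shipped mini-dictionary: terms linked in reports.
# columns: term	definition
disulfide bond	Covalent bond between the sulfur atoms of two cysteine side chains; stabilizes the folded structure.
salt bridge	Close-range ionic interaction between a negatively charged (aspartate/glutamate) and a positively charged (lysine/arginine/histidine) side chain.
hydrogen bond	Weak directional interaction between a donor hydrogen and an acceptor atom; the main determinant of secondary structure.
alpha-helix	Helical secondary-structure element held together by hydrogen bonds between residue i and residue i+4.
beta-strand	Extended secondary-structure element; strands pair into sheets through backbone hydrogen bonds.
transmembrane domain	Protein segment that spans the lipid bilayer; usually hydrophobic and often helical.
phosphorylation	Post-translational attachment of a phosphate group to a serine, threonine or tyrosine side chain.
conservation	Tendency of a sequence position to retain the same amino acid across homologous proteins.
hydrophobicity	Degree to which a residue avoids water; hydrophobic residues prefer the protein core.
solvent accessibility	Surface area of a residue that a water-sized probe can reach; buried residues have low accessibility.
homology model	3D model of a protein built on the experimentally solved structure of a sequence-similar template.
active site	Region of an enzyme where substrate binding and catalysis take place.
cysteine	Amino acid with a thiol side chain; the only residue that can form disulfide bonds.
proline	Amino acid whose side chain closes a ring onto its own backbone nitrogen; rigid, and a known breaker of alpha-helices.
voltage sensor	Charged transmembrane segment of an ion channel that moves in response to membrane potential.
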