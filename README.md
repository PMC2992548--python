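# mutexplain

**mutexplain** explains the likely structural and functional consequences of
a single amino-acid substitution (a missense mutation) in a protein, in
prose a biomedical researcher can read — not a table of scores. It is aimed
at human-genetics and molecular-biology groups who find a variant of
interest and want a first mechanistic hypothesis: *does this substitution
break a disulfide bond, disrupt a helix, bury a charge, destroy a
phosphorylation site, or hit an invariant position?*

Everything runs locally on files you supply: a sequence (FASTA), the
mutation, and optionally a 3D structure (PDB format — a deposited structure
or a homology model), a multiple sequence alignment (aligned FASTA), tables
of curated or predicted per-residue annotations, and metadata about
candidate template structures.

## How it works

1. **Structure-derived features.** If a structure is given, the package
   computes per residue: solvent-accessible surface area by the
   Shrake–Rupley method (960-point deterministic spiral lattice, probe
   1.4 Å), relative accessibility RSA = ASA / maxASA with burial classes
   (BURIED < 0.07 ≤ PARTIALLY_BURIED < 0.25 ≤ EXPOSED), backbone hydrogen
   bonds under the DSSP electrostatic model
   *E* = 0.084·332·(1/r₍ON₎ + 1/r₍CH₎ − 1/r₍OH₎ − 1/r₍CN₎) kcal/mol
   (bond if *E* < −0.5), a simplified helix/strand/coil assignment from the
   bond pattern, disulfide bridges (SG–SG ≤ 2.5 Å), salt bridges
   (carboxyl O to basic N ≤ 4.0 Å), ligand/ion contacts (≤ 4.0 Å to a
   non-water hetero group) and a packing density used as a clash-risk
   proxy.
2. **Numbering reconciliation.** Sequences from different sources rarely
   agree on numbering (signal peptides, tags, unresolved loops). All
   annotation transfer goes through a global Needleman–Wunsch/Gotoh
   alignment (BLOSUM62, gap open 10, extend 0.5) whose aligned columns
   define a monotone position mapping.
3. **Annotation store with source ranking.** All features live in one
   per-protein store in four categories (contacts, variable features, fixed
   features, variants). When the same feature type is available from
   several sources, conclusions use only the most reliable tier:
   **structure-derived > curated > predicted**; suppressed records are kept
   as corroboration.
4. **Conservation.** Per-column relative amino-acid frequencies from the
   alignment give a verdict per position (INVARIANT / HIGHLY_CONSERVED /
   CONSERVED / VARIABLE) and whether the mutant residue was ever observed
   there.
5. **Six-branch decision scheme.** A declarative rule catalogue produces
   one report paragraph per aspect, in fixed order: **Contacts, Structural
   domain, Modifications, Variants, Conservation, Amino acid properties**.
   The last branch always speaks — even with no annotations at all, the
   size/charge/hydrophobicity differences (Zamyatnin volumes,
   Kyte–Doolittle scale, formal charge at pH 7) support a conclusion.
   Rules fired on prediction-only evidence are downgraded one severity
   step.
6. **Template triage.** Given candidate-structure metadata, the package
   decides between using a deposited structure (100% identity, covers the
   mutation), accepting a homology model (alignment identity above the
   length-dependent twilight-zone threshold t(L) = 290.15·L^(−0.562),
   plateau 24.8% for L > 80), warning when the margin is below 5 points,
   or falling back to sequence-only mode.

Reports are rendered as self-contained Markdown (with a linked glossary of
technical terms) and as schema-validated JSON; identical inputs give
byte-identical output.

## Worked example

Analyse a serine-to-alanine substitution at a phosphorylation site,
with a curated feature table and a small alignment:

```bash
cat > seq.fasta << 'EOF'
>KIN1
MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQA
EOF

cat > features.tsv << 'EOF'
KIN1	CURATED	FIXED	PHOSPHO_SITE	17	17	.	.	protein kinase A target site
KIN1	CURATED	FIXED	DOMAIN	10	25	.	.	kinase docking region
EOF

cat > msa.fasta << 'EOF'
>KIN1
MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQA
>HOM2
MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQA
>HOM3
MKSAYIAKQRQISFVKSHFSRQLEERLGMIEVQA
>HOM4
MKTAYIAKQRQISFVKSHFSKQLEERLGLIEVQA
EOF

mutexplain --sequence seq.fasta --mutation S17A \
           --features features.tsv --msa msa.fasta
```

The report's aspect sections read (abridged):

```
## Structural domain

**[INFO]** Position 17 lies in an annotated region (kinase docking region);
a substitution here can affect the function associated with this region.

## Modifications

**[SEVERE]** The wild-type serine at position 17 is a phosphorylation site.
The mutant alanine cannot accept a phosphate group, so this modification is
abolished, which can disturb signalling.

## Conservation

**[SEVERE]** Position 17 is invariant in the multiple sequence alignment
(wild-type frequency 100%), and alanine was never observed there. Mutation
of such a conserved residue is likely to be damaging.

## Amino acid properties

**[INFO]** The wild-type residue is serine and the mutant residue is
alanine. The mutant residue is smaller than the wild-type residue (-0.4
cubic Angstrom). The mutant residue is more hydrophobic (+2.6 on the
hydrophobicity scale).
```

Reading it: the substitution is structurally mild (serine and alanine are
nearly the same size), but it abolishes a known phosphorylation site at a
position that never varies across homologues — two independent SEVERE
signals that the variant is likely damaging through loss of regulation,
not through misfolding.

Structures are equally easy: pass `--structure model.pdb` and the report
gains burial, secondary-structure and contact evidence computed from the
coordinates (try a leucine-to-proline substitution inside a helix).

## Layout

```
src/mutexplain/
  aa_knowledge.py      amino-acid property tables and substitution deltas
  bio_io.py            FASTA/PDB/MSA/feature-table IO + fixture generator
  residue_mapping.py   global alignment and position mapping
  structure_features.py ASA, H-bonds, secondary structure, contacts, packing
  conservation.py      per-column alignment frequencies and verdicts
  feasibility.py       structure/model/sequence-only triage and ranking
  annotation_store.py  per-residue store with source-tier resolution
  decision_engine.py   the six-branch rule catalogue
  report.py            Markdown/JSON rendering and glossary linking
  cli.py               the `mutexplain` command
  data/                property tables, rule catalogue, sentences, glossary
docs/methods.md        models, parameters, numerical choices, limitations
```
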