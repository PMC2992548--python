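# Methods

This note records the models, parameters and numerical choices behind
`mutexplain`, what the synthetic test structures do and do not emulate, and
the known limitations. All numeric parameters live in
`mutexplain.config.RunConfig`; every report echoes them in its provenance
header so results are interpretable without reading this file.

## Amino-acid property model

Substitutions are compared on three axes:

* **Hydrophobicity** — Kyte–Doolittle scale (dimensionless, −4.5 … +4.5).
* **Size** — Zamyatnin residue volumes in Å³.
* **Charge** — formal side-chain charge at pH 7: −1 for Asp/Glu, +1 for
  Lys/Arg, 0 otherwise. Histidine is treated as neutral; its pKa lies close
  enough to physiological pH that either convention is defensible, and the
  neutral choice avoids overcalling "charge lost" findings for the common
  His substitutions.

Deltas are mutant − wild-type, so the comparison is antisymmetric by
construction. A change is *significant* (rule-triggering) when
|Δhydrophobicity| ≥ 1.0, |Δvolume| ≥ 30 Å³, or Δcharge ≠ 0. These
thresholds are conventions, not fits: 1.0 is a quarter of the
hydrophobicity scale's range, 30 Å³ roughly one CH₂-group-sized step
between adjacent residue volumes. Both are config keys.

Boolean chemistry is carried as flags: helix breakers {P, G}, the sole
disulfide-capable residue {C}, phospho-acceptors {S, T, Y}, aromatics,
and flexibility {G}. The table ships as tab-separated text
(`data/aa_properties.tsv`) and can be swapped via config; the chosen scales
are stated in the report provenance rather than asserted as canonical.

## Accessible surface area

Shrake–Rupley numerical integration: each heavy atom's sphere of radius
r_vdw + r_probe is sampled on a deterministic spiral (Fibonacci) lattice of
960 points; a point is accessible if it lies outside every neighbour's
expanded sphere. Radii are united-atom Chothia-style values C 1.87, N 1.65,
O 1.40, S 1.85 Å (1.80 Å default for anything else), probe 1.4 Å.
960 points keep the isolated-sphere error well under 1% and agree with a
4000-point run to better than 2% on every test structure, while keeping a
full-protein pass fast. Determinism was preferred over random sampling so
identical runs produce identical reports. Because the lattice is fixed in
the world frame, ASA is invariant under rigid motions only up to the
lattice's angular resolution (tested at ±5%/2 Å² tolerance).

RSA divides by the residue type's theoretical maximum ASA (Tien et al.
table, shipped as data), capped at 1.2 for extended conformations. Burial
classes: BURIED < 0.07 ≤ PARTIALLY_BURIED < 0.25 ≤ EXPOSED — common
structural-biology conventions, config-adjustable.

## Hydrogen bonds and secondary structure

Backbone N–H···O=C bonds use the DSSP electrostatic model,
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, accepted below
−0.5 kcal/mol. Structures without hydrogens get the amide H placed
geometrically: 1.0 Å from N along the direction opposite the bisector of
N→C(prev) and N→CA. Prolines and chain-initial residues cannot donate.
Donors and acceptors may sit on different chains (inter-chain sheets);
within a chain, neighbours at |i−j| < 2 are excluded.

Secondary structure is a deliberately simplified DSSP: H where two
consecutive i+4→i turns overlap (minimal-helix rule, marking residues
i+1…i+4), E for residues in parallel or antiparallel bridge patterns of
paired bonds, C otherwise. No 3₁₀/π/turn/bend subclasses — the decision
rules only distinguish helix, strand and coil.

## Contacts and packing

* Disulfides: CYS SG–SG ≤ 2.5 Å, each SG in at most one pair
  (closest-first greedy matching).
* Salt bridges: any Asp/Glu carboxyl O within 4.0 Å of a Lys NZ,
  Arg NH1/NH2/NE or His ND1/NE2 nitrogen.
* Ligand/ion contacts: polymer heavy atom within 4.0 Å of a non-water
  hetero group's heavy atom; single-atom metal species are flagged ION.
* Packing density: heavy atoms of other residues within 6.0 Å of the
  side-chain centroid (CA for glycine). A count ≥ 20 counts as densely
  packed. This is the clash-risk proxy used when a buried position gains
  ≥ 30 Å³ of side-chain volume: no published algorithm exists for the
  "does the bigger side chain fit" question at this level of description,
  so the package uses this honest geometric heuristic and labels the
  resulting finding accordingly. A fixed threshold was chosen over a
  per-protein median because the engine answers single-residue queries and
  must give the same answer regardless of what else was computed.

All structure-derived facts are exported as STRUCTURE-tier feature records
re-numbered onto the submitted sequence, so the decision engine consumes
them through the same ranked store as curated and predicted annotations.

## Numbering reconciliation

Global pairwise alignment (Gotoh affine-gap dynamic programming) with
BLOSUM62, gap open 10, extend 0.5; a k-long gap costs open + (k−1)·extend.
Ties break deterministically: substitution over gap-in-second over
gap-in-first. Aligned columns define a strictly monotone 1-based mapping;
identity is computed over the aligned region excluding terminal gaps.
Structural feature transfer refuses to proceed when the mapped-region
identity falls below 30% — below that, position equivalence is guesswork.
The aligner is cross-checked in the test suite against an independent
implementation and against exhaustive enumeration of all alignments on
small instances.

## Conservation

Per-column relative frequencies over non-gap symbols; columns where the
reference row has a gap carry no reference position and are skipped. No
sequence weighting is applied — weighting schemes differ between databases
and none is uniquely standard, and the unweighted count is exactly
reproducible from the alignment alone; the per-column support (n_effective)
is reported so low-support columns are visible. Verdict bands:
INVARIANT (wild-type frequency = 1.0), HIGHLY_CONSERVED (≥ 0.9),
CONSERVED (≥ 0.5), VARIABLE (< 0.5); positions outside the profile give
NO_DATA and the conservation branch stays silent.

## Template triage

The length-dependent identity threshold is t(L) = 290.15·L^(−0.562) for
alignments of 10–80 residues, floored at and plateauing to 24.8% beyond
(the floor keeps the curve monotone where the power law dips under its
asymptote near L = 80; the step at the boundary is < 0.2 points).
A candidate 100% identical and covering the mutated residue is used
directly; a margin of ≥ 5 percentage points above the curve accepts a
model silently; 0–5 points accepts with a warning (the band is read as
percentage points, matching the parallel band such plots draw); a negative
margin, or a candidate not covering the mutation, forces sequence-only
mode. Ranking of multiple candidates: covers-the-mutation first, then
experimental method (X-ray > EM > NMR > other), then resolution ascending,
then query coverage descending, then id. Method is sorted before
resolution because NMR entries carry no resolution and would otherwise
always sink to the bottom ambiguously; `ranking_order: resolution_first`
restores the literal resolution-first order.

## Decision scheme

The six branches run in fixed order (contacts, structural domain,
modifications, variants, conservation, amino-acid properties); each
contributes zero or more findings except properties, which always
speaks. The rule inventory (~20 rules) is a shipped YAML catalogue —
rule id, branch, predicate list, base severity, sentence key — evaluated
against a predicate context computed once per request; phrasing lives in a
separate sentence-template catalogue, so logic and language can evolve
independently and users can extend either. Severities {INFO, MODERATE,
SEVERE} are an ordinal convenience for machine consumers; the prose is the
primary output. Rules marked tier-sensitive are downgraded one severity
step when their best evidence is prediction-only, which encodes the source
ranking into the conclusions' confidence. Within a branch, findings sort
by severity then sentence key; the whole output is deterministic.

## Synthetic test structures

The fixture generator builds minimal structures with known ground truth:
an ideal poly-Ala α-helix (φ = −57°, ψ = −47°, ideal bond geometry), a
fully extended chain, an antiparallel two-strand pair, a disulfide pair
(SG–SG = 2.05 Å), a salt bridge (NZ–OE1 = 3.5 Å), a His–Zn²⁺ site
(2.2 Å), and a residue enclosed by a 64-atom shell (fully buried, densely
packed). The strand pair is built from one β-strand and its antiparallel
dyad image, grid-searching the rigid placement that maximizes inter-strand
backbone bonds under the same electrostatic criterion the detector uses —
a construction aid, not an oracle: the emitted manifest lists the
mutually-bonded bridge residues, and the detectors must re-derive them
from the coordinates alone.

These fixtures emulate *geometry*, not proteins: no side chains beyond
what each site needs, no solvent, no thermal disorder, no experimental
noise, idealized bond lengths. Passing tests therefore demonstrate that
the geometric detectors implement their definitions correctly — not that
those definitions capture every real-world structure quirk (alternate
conformations beyond altloc A, chain breaks, non-standard residues are
handled conservatively: skipped with warnings).

## Degenerate inputs and tie-breaks

Single-residue chains align and map; single-row alignments give frequency
1.0 everywhere; a position with no annotations yields an empty per-residue
view and only a properties paragraph; equal-distance disulfide partners
resolve closest-first with residue order as the final tie-break; candidate
ranking ends in a lexicographic id comparison so no ties survive. Reports
for empty branches print an explicit "no information" line rather than
omitting the section, keeping the six-section contract byte-stable.

## Known limitations

* Findings are qualitative; no ΔΔG, no pathogenicity probability, and no
  calibration against variant databases is claimed.
* Sequence-only mode cannot see burial, packing or contacts; its
  properties paragraph is correspondingly neutral.
* The secondary-structure simplification can miss short 3₁₀ segments that
  full DSSP would call helical.
* Conservation is unweighted relative frequency; deep alignments of
  redundant sequences will overstate invariance.
* One substitution per run; compound variants are out of scope.
* Analyses use the first model of multi-model files and altloc A only.
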