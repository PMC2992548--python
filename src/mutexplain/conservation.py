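"""Per-column conservation from a user-supplied multiple sequence alignment.

Conservation of a position is the relative frequency of each amino-acid
type in that alignment column, computed over non-gap symbols only (the
statement is about amino acids, not about gaps); the number of non-gap
sequences at the column is reported so that low-support columns remain
visible.  No sequence weighting is applied, which keeps the numbers exactly
reproducible from the alignment alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mutexplain.bio_io import SequenceRecord
from mutexplain.config import RunConfig

GAP = "-"

VERDICTS = ("INVARIANT", "HIGHLY_CONSERVED", "CONSERVED", "VARIABLE", "NO_DATA")


@dataclass
class ColumnProfile:
    position: int                 # 1-based on the reference sequence
    reference_residue: str
    frequencies: dict             # residue code -> relative frequency
    wild_type_frequency: float
    consensus: str
    n_effective: int              # sequences with a non-gap at this column


@dataclass
class ConservationProfile:
    reference_id: str
    columns: dict = field(default_factory=dict)  # position -> ColumnProfile
    warnings: list = field(default_factory=list)

    def get(self, position: int) -> ColumnProfile | None:
        return self.columns.get(position)


@dataclass
class ConservationVerdict:
    verdict: str
    wild_frequency: float | None = None
    mutant_frequency: float | None = None
    mutant_observed: bool = False
    consensus: str | None = None
    n_effective: int = 0


def column_frequencies(
    msa: list[SequenceRecord], reference_id: str | None = None
) -> ConservationProfile:
    """Build a conservation profile over the reference row's positions.

    Columns where the reference carries a gap have no reference position
    and are skipped.  Frequencies are over non-gap symbols and sum to one.
    """
    if not msa:
        raise ValueError("empty alignment")
    if reference_id is None:
        reference_id = msa[0].id
    ref = next((r for r in msa if r.id == reference_id), None)
    if ref is None:
        raise ValueError(f"reference id {reference_id!r} not present in alignment")
    profile = ConservationProfile(reference_id=reference_id)
    pos = 0
    for col in range(len(ref.residues)):
        ref_res = ref.residues[col]
        if ref_res == GAP:
            continue
        pos += 1
        counts: dict[str, int] = {}
        for row in msa:
            sym = row.residues[col]
            if sym == GAP:
                continue
            counts[sym] = counts.get(sym, 0) + 1
        n_eff = sum(counts.values())
        freqs = {code: c / n_eff for code, c in counts.items()}
        consensus = max(sorted(freqs), key=lambda c: freqs[c])
        if n_eff == 1 and len(msa) > 1:
            profile.warnings.append(
                f"position {pos}: only the reference is aligned (low support)"
            )
        profile.columns[pos] = ColumnProfile(
            position=pos,
            reference_residue=ref_res,
            frequencies=freqs,
            wild_type_frequency=freqs.get(ref_res, 0.0),
            consensus=consensus,
            n_effective=n_eff,
        )
    return profile


def score_mutation(
    profile: ConservationProfile | None,
    position: int,
    wild: str,
    mutant: str,
    config: RunConfig | None = None,
) -> ConservationVerdict:
    """Verdict for one substitution from the profile's frequency bands.

    INVARIANT when the wild-type is the only residue ever observed,
    HIGHLY_CONSERVED / CONSERVED / VARIABLE by the configured thresholds,
    NO_DATA when the position is not covered by the profile.
    """
    cfg = config or RunConfig()
    col = profile.get(position) if profile is not None else None
    if col is None:
        return ConservationVerdict(verdict="NO_DATA")
    wf = col.frequencies.get(wild.upper(), 0.0)
    mf = col.frequencies.get(mutant.upper(), 0.0)
    if wf >= cfg.conservation_invariant:
        verdict = "INVARIANT"
    elif wf >= cfg.conservation_high:
        verdict = "HIGHLY_CONSERVED"
    elif wf >= cfg.conservation_mid:
        verdict = "CONSERVED"
    else:
        verdict = "VARIABLE"
    return ConservationVerdict(
        verdict=verdict,
        wild_frequency=wf,
        mutant_frequency=mf,
        mutant_observed=mf > 0.0,
        consensus=col.consensus,
        n_effective=col.n_effective,
    )


def profile_to_tsv(profile: ConservationProfile, mutant_by_pos: dict | None = None) -> str:
    """Dump per-position conservation as TSV for inspection."""
    lines = ["#position\twild\tconsensus\twild_freq\tmutant_freq\tn_effective"]
    mutant_by_pos = mutant_by_pos or {}
    for pos in sorted(profile.columns):
        col = profile.columns[pos]
        mut = mutant_by_pos.get(pos)
        mf = col.frequencies.get(mut, 0.0) if mut else ""
        lines.append(
            f"{pos}\t{col.reference_residue}\t{col.consensus}\t"
            f"{col.wild_type_frequency:.4f}\t"
            f"{mf if mf == '' else format(mf, '.4f')}\t{col.n_effective}"
        )
    return "\n".join(lines) + "\n"
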