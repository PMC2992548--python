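"""Static amino-acid property tables and pairwise substitution comparison.

The table (one row per standard residue) ships as plain text so the scales
are data, not code: hydrophobicity on the Kyte-Doolittle scale, residue
volumes after Zamyatnin (cubic Angstrom), and formal side-chain charge at
pH 7 with histidine treated as neutral.  Flags mark chemistry the decision
scheme cares about: helix breakers (P, G), the only disulfide-capable
residue (C), phospho-acceptors (S, T, Y), aromatics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import FrozenSet

VALID_FLAGS = frozenset(
    {"HELIX_BREAKER", "FLEXIBLE", "DISULFIDE_CAPABLE", "PHOSPHO_ACCEPTOR", "AROMATIC"}
)

#: ambiguous / non-standard one-letter codes we reject explicitly
AMBIGUOUS_CODES = frozenset("BJOUXZ")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


@dataclass(frozen=True)
class AminoAcidProperties:
    code: str
    name: str
    hydrophobicity: float  # Kyte-Doolittle, dimensionless
    volume: float          # Zamyatnin, cubic Angstrom
    charge: int            # {-1, 0, +1} at pH 7
    flags: FrozenSet[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class PropertyDelta:
    """Differences mutant minus wild-type, with human-readable labels."""

    wild: str
    mutant: str
    d_hydrophobicity: float
    d_volume: float
    d_charge: int
    gained_flags: FrozenSet[str]
    lost_flags: FrozenSet[str]
    direction_labels: dict


@lru_cache(maxsize=None)
def _load_table(path: str) -> dict:
    table: dict[str, AminoAcidProperties] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, got {len(parts)}"
                )
            code, name, hydro, vol, charge, flags = parts
            flagset = frozenset() if flags == "." else frozenset(flags.split(","))
            unknown = flagset - VALID_FLAGS
            if unknown:
                raise ValueError(f"{path}:{lineno}: unknown flag(s) {sorted(unknown)}")
            table[code] = AminoAcidProperties(
                code=code,
                name=name,
                hydrophobicity=float(hydro),
                volume=float(vol),
                charge=int(charge),
                flags=flagset,
            )
    if len(table) != 20:
        raise ValueError(f"{path}: expected 20 amino acids, found {len(table)}")
    return table


def get_properties(code: str, table_path: str | None = None) -> AminoAcidProperties:
    """Look up the property row for a one-letter residue code.

    Case-insensitive; three-letter codes are accepted and normalized.
    Ambiguous or non-standard codes (B, J, O, U, X, Z) are rejected.
    """
    if table_path is None:
        from mutexplain.config import RunConfig

        table_path = RunConfig().aa_table
    table = _load_table(table_path)
    c = code.strip().upper()
    if len(c) == 3 and c in THREE_TO_ONE:
        c = THREE_TO_ONE[c]
    if len(c) != 1 or c in AMBIGUOUS_CODES or c not in table:
        raise ValueError(f"not a standard amino-acid code: {code!r}")
    return table[c]


def _charge_label(wild: int, mut: int) -> str:
    if wild == mut:
        return "charge unchanged"
    if wild != 0 and mut != 0 and wild != mut:
        return "charge flipped"
    if mut != 0:
        return "charge gained"
    return "charge lost"


def compare_residues(
    wild: str, mutant: str, table_path: str | None = None
) -> PropertyDelta:
    """Numeric property deltas (mutant minus wild-type) plus labels.

    Antisymmetric in its arguments for the three numeric fields; the
    identity substitution yields an all-zero delta with empty flag sets.
    """
    w = get_properties(wild, table_path)
    m = get_properties(mutant, table_path)
    d_h = round(m.hydrophobicity - w.hydrophobicity, 10)
    d_v = round(m.volume - w.volume, 10)
    d_c = m.charge - w.charge
    labels = {
        "size": "larger" if d_v > 0 else ("smaller" if d_v < 0 else "same size"),
        "hydrophobicity": (
            "more hydrophobic"
            if d_h > 0
            else ("less hydrophobic" if d_h < 0 else "equally hydrophobic")
        ),
        "charge": _charge_label(w.charge, m.charge),
    }
    return PropertyDelta(
        wild=w.code,
        mutant=m.code,
        d_hydrophobicity=d_h,
        d_volume=d_v,
        d_charge=d_c,
        gained_flags=m.flags - w.flags,
        lost_flags=w.flags - m.flags,
        direction_labels=labels,
    )


def special_flags_for_context(
    mutant: str, wild: str, table_path: str | None = None
) -> dict:
    """Flag transitions the decision branches key on.

    Returns, for each flag, whether it was gained, lost, or retained by the
    substitution (absent flags are omitted).
    """
    w = get_properties(wild, table_path)
    m = get_properties(mutant, table_path)
    out: dict[str, str] = {}
    for flag in VALID_FLAGS:
        in_w, in_m = flag in w.flags, flag in m.flags
        if in_w and in_m:
            out[flag] = "retained"
        elif in_m:
            out[flag] = "gained"
        elif in_w:
            out[flag] = "lost"
    return out
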