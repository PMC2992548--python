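"""Run configuration: every tunable parameter, pinned and documented.

All cutoffs, scales and curve constants used anywhere in the pipeline live
here so that (a) a report's provenance header can echo the exact numbers a
run used, and (b) a user can override any of them from a YAML file without
touching code.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml


def _data_path(name: str) -> str:
    return str(resources.files("mutexplain").joinpath("data", name))


@dataclass
class RunConfig:
    """All pinned parameters of the analysis pipeline.

    Attributes are grouped by the stage they control; defaults are the
    values echoed in every report's provenance header.
    """

    # --- amino-acid property tables -------------------------------------
    #: tab-delimited property table (code, name, hydrophobicity, volume,
    #: charge, flags); hydrophobicity is Kyte-Doolittle, volume Zamyatnin.
    aa_table: str = field(default_factory=lambda: _data_path("aa_properties.tsv"))
    #: per-residue maximum ASA reference used for RSA (square Angstrom).
    max_asa_table: str = field(default_factory=lambda: _data_path("max_asa.tsv"))

    # --- "significant difference" thresholds for branch triggering ------
    #: |delta hydrophobicity| at or above this is a significant change.
    hydrophobicity_threshold: float = 1.0
    #: |delta volume| (cubic Angstrom) at or above this is a significant change.
    volume_threshold: float = 30.0

    # --- pairwise alignment (numbering reconciliation) -------------------
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    #: refuse to transfer annotations when the mapped-region identity is lower.
    min_mapping_identity: float = 0.30

    # --- accessible surface area -----------------------------------------
    probe_radius: float = 1.4
    asa_points: int = 960
    #: element -> van der Waals radius (Angstrom), Chothia-style united atoms.
    vdw_radii: dict = field(
        default_factory=lambda: {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85}
    )
    vdw_default: float = 1.80
    #: RSA below this is BURIED; between the two, PARTIALLY_BURIED.
    buried_rsa: float = 0.07
    exposed_rsa: float = 0.25
    #: RSA is capped here (extended conformations can exceed the reference).
    rsa_cap: float = 1.2

    # --- hydrogen bonds / secondary structure -----------------------------
    #: acceptance cutoff for the electrostatic H-bond energy (kcal/mol).
    hbond_energy_cutoff: float = -0.5
    #: N-H bond length used when placing the missing amide hydrogen.
    amide_h_length: float = 1.0

    # --- other structural detectors ---------------------------------------
    disulfide_cutoff: float = 2.5
    salt_bridge_cutoff: float = 4.0
    ligand_contact_cutoff: float = 4.0
    packing_radius: float = 6.0
    #: neighbour count at or above this counts as densely packed.
    packing_dense_threshold: int = 20

    # --- conservation verdict bands ----------------------------------------
    conservation_invariant: float = 1.0
    conservation_high: float = 0.9
    conservation_mid: float = 0.5

    # --- modelling feasibility (length-dependent identity threshold) --------
    curve_coefficient: float = 290.15
    curve_exponent: float = -0.562
    curve_plateau: float = 24.8
    curve_plateau_length: int = 80
    #: width (percentage points) of the warning band above the threshold.
    warn_band: float = 5.0
    #: candidate ranking key order; the alternative "resolution_first" sorts
    #: resolution before experimental method.
    ranking_order: str = "method_first"

    def override(self, updates: dict) -> "RunConfig":
        """Return a copy with ``updates`` applied; unknown keys are rejected."""
        known = {f.name for f in dataclasses.fields(self)}
        bad = sorted(set(updates) - known)
        if bad:
            raise KeyError(f"unknown config key(s): {', '.join(bad)}")
        return dataclasses.replace(self, **updates)

    def provenance(self) -> dict:
        """Flat, JSON-friendly view of every pinned parameter."""
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Path):
                v = str(v)
            out[f.name] = v
        return out


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig, applying YAML ``key: value`` overrides if given."""
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must be a mapping of key: value")
    return cfg.override(data)
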