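"""Shared fixtures: synthetic structures, annotation stores, oracles."""

from __future__ import annotations

import math

import pytest

from mutexplain.annotation_store import AnnotationStore
from mutexplain.bio_io import FeatureRecord, make_fixture, read_pdb
from mutexplain.config import RunConfig


@pytest.fixture(scope="session")
def cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def helix():
    """12-residue ideal poly-Ala helix: (structure, manifest)."""
    pdb, manifest = make_fixture("ideal_helix", 12)
    return read_pdb(pdb), manifest


@pytest.fixture(scope="session")
def extended_chain():
    pdb, manifest = make_fixture("extended", 10)
    return read_pdb(pdb), manifest


@pytest.fixture(scope="session")
def sheet():
    pdb, manifest = make_fixture("antiparallel_sheet", 12)
    return read_pdb(pdb), manifest


@pytest.fixture(scope="session")
def disulfide_site():
    pdb, manifest = make_fixture("disulfide_pair", 4)
    return read_pdb(pdb), manifest


@pytest.fixture(scope="session")
def salt_bridge_site():
    pdb, manifest = make_fixture("salt_bridge", 4)
    return read_pdb(pdb), manifest


@pytest.fixture(scope="session")
def metal_site():
    pdb, manifest = make_fixture("metal_site", 4)
    return read_pdb(pdb), manifest


@pytest.fixture(scope="session")
def clash_core():
    pdb, manifest = make_fixture("clash_core", 4)
    return read_pdb(pdb), manifest


def store_with(sequence: str, records: list, seq_id: str = "P1") -> AnnotationStore:
    """Annotation store for a submitted sequence with records pre-ingested."""
    store = AnnotationStore(seq_id=seq_id, sequence=sequence)
    store.ingest(records)
    return store


def record(sequence_id="P1", tier="CURATED", category="FIXED", ftype="DOMAIN",
           begin=1, end=1, value=None, partner=None, description=""):
    return FeatureRecord(
        seq_id=sequence_id, source_tier=tier, category=category,
        feature_type=ftype, begin=begin, end=end, value=value,
        partner=partner, description=description,
    )


# ---------------------------------------------------------------------------
# independent alignment oracle: enumerate every global alignment recursively


def brute_force_align_score(a: str, b: str, mat, gap_open: float,
                            gap_extend: float) -> float:
    """Best global-alignment score by exhaustive enumeration of alignments.

    A gap run of length k costs open + (k-1)*extend.  No dynamic
    programming: plain recursion over the three possible next columns,
    carrying only which operation produced the previous column.
    """

    def sub(x, y):
        return float(mat[x, y])

    n, m = len(a), len(b)

    def rec(i: int, j: int, last: str) -> float:
        if i == n and j == m:
            return 0.0
        best = -math.inf
        if i < n and j < m:
            best = max(best, sub(a[i], b[j]) + rec(i + 1, j + 1, "M"))
        if i < n:
            cost = gap_extend if last == "X" else gap_open
            best = max(best, -cost + rec(i + 1, j, "X"))
        if j < m:
            cost = gap_extend if last == "Y" else gap_open
            best = max(best, -cost + rec(i, j + 1, "Y"))
        return best

    return rec(0, 0, "")
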