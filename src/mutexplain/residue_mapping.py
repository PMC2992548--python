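"""Reconcile residue numbering between sequences from different sources.

Sequences describing the same protein rarely agree on numbering: curated
database entries often include the signal peptide while structure files
lack it, constructs carry tags, and structures have unresolved stretches.
All annotation transfer therefore goes through a global pairwise alignment
(Needleman-Wunsch/Gotoh with affine gaps, BLOSUM62 by default) whose
aligned columns define a strictly monotone position-to-position mapping.

The aligner is implemented here rather than delegated so that scoring and
tie-breaking are pinned exactly: at equal score a substitution is preferred
over a gap in the second sequence, which is preferred over a gap in the
first.  Gap cost for a run of length k is ``open + (k - 1) * extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

UNMAPPED = None

_NEG = -1e18


@dataclass
class Alignment:
    a: str
    b: str
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def columns(self) -> list[tuple[int | None, int | None]]:
        """Per-column 1-based positions, None where a sequence has a gap."""
        out = []
        i = j = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            pa = pb = None
            if ca != "-":
                i += 1
                pa = i
            if cb != "-":
                j += 1
                pb = j
            out.append((pa, pb))
        return out


@dataclass
class ResidueMapping:
    """Monotone mapping between two 1-based coordinate systems."""

    pairs: list[tuple[int, int]]
    identity_fraction: float
    aligned_length: int

    def __post_init__(self):
        self._fwd = dict(self.pairs)
        self._rev = {t: s for s, t in self.pairs}

    @classmethod
    def identity(cls, length: int) -> "ResidueMapping":
        pairs = [(i, i) for i in range(1, length + 1)]
        return cls(pairs=pairs, identity_fraction=1.0, aligned_length=length)

    def inverse(self) -> "ResidueMapping":
        return ResidueMapping(
            pairs=[(t, s) for s, t in self.pairs],
            identity_fraction=self.identity_fraction,
            aligned_length=self.aligned_length,
        )

    def to_tsv(self) -> str:
        return "\n".join(f"{s}\t{t}" for s, t in self.pairs) + "\n"


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


def _score(mat, x: str, y: str) -> float:
    try:
        return float(mat[x, y])
    except KeyError:
        return float(mat["X", "X"]) if ("X", "X") in mat else 0.0


def align_global(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Optimal global alignment of two residue strings (Gotoh algorithm).

    Affine gap cost ``open + (k - 1) * extend`` for a k-long gap.
    Deterministic: ties resolved substitution > gap-in-b > gap-in-a.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    mat = _matrix(matrix)
    n, m = len(a), len(b)
    # state matrices: M substitution, X gap in b (a consumed), Y gap in a
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(mat, a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] - gap_open,
                X[i - 1, j] - gap_extend,
                Y[i - 1, j] - gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] - gap_open,
                X[i, j - 1] - gap_open,
                Y[i, j - 1] - gap_extend,
            )
    finals = (M[n, m], X[n, m], Y[n, m])
    score = max(finals)
    # traceback, preferring M > X > Y at every tie
    state = int(np.argmax(np.array(finals)))  # argmax takes the first max: M first
    i, j = n, m
    ra, rb = [], []
    eps = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # M: a[i-1] ~ b[j-1]
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            s = _score(mat, a[i - 1], b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            state = _pick(M[i, j], X[i, j], Y[i, j], target, eps)
        elif state == 1:  # X: a[i-1] ~ gap
            ra.append(a[i - 1])
            rb.append("-")
            val = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - gap_open - val) < eps:
                state = 0
            elif abs(X[i, j] - gap_extend - val) < eps:
                state = 1
            else:
                state = 2
        else:  # Y: gap ~ b[j-1]
            ra.append("-")
            rb.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if abs(M[i, j] - gap_open - val) < eps:
                state = 0
            elif abs(Y[i, j] - gap_extend - val) < eps:
                state = 2
            else:
                state = 1
    return Alignment(
        a=a, b=b,
        aligned_a="".join(reversed(ra)),
        aligned_b="".join(reversed(rb)),
        score=float(score),
    )


def _pick(m_val: float, x_val: float, y_val: float, target: float, eps: float) -> int:
    if abs(m_val - target) < eps:
        return 0
    if abs(x_val - target) < eps:
        return 1
    return 2


def build_mapping(alignment: Alignment) -> ResidueMapping:
    """One (source, target) pair per aligned non-gap column, monotone."""
    pairs = []
    matches = 0
    cols = alignment.columns
    # aligned_length excludes terminal gap columns
    non_term = [k for k, (pa, pb) in enumerate(cols) if pa is not None and pb is not None]
    if not non_term:
        return ResidueMapping(pairs=[], identity_fraction=0.0, aligned_length=0)
    first, last = non_term[0], non_term[-1]
    aligned_length = last - first + 1
    for k in range(first, last + 1):
        pa, pb = cols[k]
        if pa is not None and pb is not None:
            pairs.append((pa, pb))
            if alignment.aligned_a[k] == alignment.aligned_b[k]:
                matches += 1
    return ResidueMapping(
        pairs=pairs,
        identity_fraction=matches / aligned_length,
        aligned_length=aligned_length,
    )


def map_position(mapping: ResidueMapping, pos: int):
    """Map a 1-based source position; UNMAPPED (None) inside deletions."""
    if pos < 1:
        raise ValueError(f"position {pos} out of range (1-based)")
    return mapping._fwd.get(pos, UNMAPPED)


def map_sequences(a: str, b: str, config=None) -> ResidueMapping:
    """Convenience: align two sequences and build the mapping."""
    kwargs = {}
    if config is not None:
        kwargs = dict(
            matrix=config.substitution_matrix,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
        )
    return build_mapping(align_global(a, b, **kwargs))
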