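"""Structure-source triage: deposited structure, homology model, or sequence only.

A deposited structure is used directly when a candidate is 100% identical
to the submitted sequence and contains the mutated residue.  Otherwise a
homology model is acceptable when the alignment's percentage identity lies
above a length-dependent threshold curve (the classic twilight-zone
boundary): t(L) = 290.15 * L^-0.562 for alignments of 10-80 residues,
plateauing at 24.8% for longer alignments.  Identities less than five
percentage points above the curve are accepted with a warning; below the
curve, or when the mutated residue is not covered, the analysis falls back
to sequence-only mode.
"""

from __future__ import annotations

from dataclasses import dataclass

from mutexplain.config import RunConfig

METHODS = ("XRAY", "EM", "NMR", "MODEL", "OTHER")
_METHOD_PRIORITY = {"XRAY": 0, "EM": 1, "NMR": 2, "MODEL": 3, "OTHER": 4}

MODES = ("USE_STRUCTURE", "MODEL_OK", "MODEL_WARN", "SEQUENCE_ONLY")


@dataclass
class TemplateCandidate:
    id: str
    identity_percent: float
    aligned_length: int
    covers_mutation: bool
    resolution: float | None = None
    method: str = "OTHER"
    coverage_length: int = 0

    def __post_init__(self):
        if not 0.0 <= self.identity_percent <= 100.0:
            raise ValueError(f"identity {self.identity_percent} outside [0, 100]")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if self.method not in _METHOD_PRIORITY:
            raise ValueError(f"unknown experimental method {self.method!r}")


@dataclass
class FeasibilityVerdict:
    mode: str
    threshold_at_length: float | None = None
    margin: float | None = None
    candidate: TemplateCandidate | None = None


def identity_threshold(aligned_length: int, config: RunConfig | None = None) -> float:
    """Minimum % identity for structural inference at a given alignment length."""
    cfg = config or RunConfig()
    if aligned_length < 10:
        raise ValueError(
            f"threshold curve undefined for alignments shorter than 10 "
            f"residues (got {aligned_length})"
        )
    if aligned_length > cfg.curve_plateau_length:
        return cfg.curve_plateau
    # floor at the plateau so the threshold is monotone non-increasing
    return max(
        cfg.curve_coefficient * aligned_length ** cfg.curve_exponent,
        cfg.curve_plateau,
    )


def classify_template(
    candidate: TemplateCandidate, config: RunConfig | None = None
) -> FeasibilityVerdict:
    """Decide how (whether) a candidate structure can support the analysis."""
    cfg = config or RunConfig()
    if candidate.identity_percent == 100.0 and candidate.covers_mutation:
        return FeasibilityVerdict(mode="USE_STRUCTURE", candidate=candidate)
    threshold = identity_threshold(candidate.aligned_length, cfg)
    margin = candidate.identity_percent - threshold
    if not candidate.covers_mutation or margin < 0:
        mode = "SEQUENCE_ONLY"
    elif margin >= cfg.warn_band:
        mode = "MODEL_OK"
    else:
        mode = "MODEL_WARN"
    return FeasibilityVerdict(
        mode=mode, threshold_at_length=threshold, margin=margin, candidate=candidate
    )


def rank_structures(
    candidates: list[TemplateCandidate], config: RunConfig | None = None
) -> list[TemplateCandidate]:
    """Deterministic best-first ordering of candidate structures.

    Key order: covers the mutation first; then experimental method
    (X-ray > EM > NMR > other); then resolution ascending (absent counts
    worst); then query coverage descending (a full protein beats a
    fragment); id as the final lexicographic tie-break.  The alternative
    ``ranking_order: resolution_first`` sorts resolution before method.
    """
    cfg = config or RunConfig()
    if not candidates:
        raise ValueError("no candidates to rank")

    def key(c: TemplateCandidate):
        res = c.resolution if c.resolution is not None else float("inf")
        method = _METHOD_PRIORITY[c.method]
        parts = [0 if c.covers_mutation else 1]
        if cfg.ranking_order == "resolution_first":
            parts += [res, method]
        else:
            parts += [method, res]
        parts += [-c.coverage_length, c.id]
        return tuple(parts)

    return sorted(candidates, key=key)


def read_candidates(stream) -> list[TemplateCandidate]:
    """Read candidate-structure metadata TSV.

    Columns: id, identity_percent, aligned_length, covers_mutation,
    resolution ('.' if absent), method, coverage_length.
    """
    import io

    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out = []
    for lineno, raw in enumerate(stream, 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        cid, ident, alen, covers, res, method, cov = parts
        try:
            out.append(
                TemplateCandidate(
                    id=cid,
                    identity_percent=float(ident),
                    aligned_length=int(alen),
                    covers_mutation=covers.strip().lower() in ("1", "true", "yes"),
                    resolution=None if res == "." else float(res),
                    method=method.upper(),
                    coverage_length=int(cov),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    return out
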