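"""Per-protein, per-residue annotation store with source ranking.

One store is built per submitted protein.  Feature records arriving from
any source are re-numbered onto the submitted sequence through a residue
mapping, deduplicated, and retrievable per residue.  When the same type of
information is available from several sources, conclusions use only the
most reliable tier — structure-derived calculations are preferred over
curated annotations, and predictions are used only when neither is
available; suppressed lower-tier records are kept as corroboration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mutexplain.bio_io import FeatureRecord
from mutexplain.residue_mapping import ResidueMapping, map_position

#: reliability order, most reliable first
TIER_ORDER = ("STRUCTURE", "CURATED", "PREDICTED")
_TIER_RANK = {t: i for i, t in enumerate(TIER_ORDER)}


@dataclass
class ResidueAnnotation:
    position: int
    wild_type: str
    #: (category, feature_type) -> list of FeatureRecord
    groups: dict = field(default_factory=dict)

    def records(self, category: str | None = None) -> list:
        out = []
        for (cat, _), recs in sorted(self.groups.items()):
            if category is None or cat == category:
                out.extend(recs)
        return out

    def of_type(self, feature_type: str) -> list:
        out = []
        for (_, ftype), recs in sorted(self.groups.items()):
            if ftype == feature_type:
                out.extend(recs)
        return out


@dataclass
class Resolution:
    """Outcome of source ranking for one feature type at one residue."""

    best: list           # records of the single highest tier present
    corroborating: list  # suppressed lower-tier records
    tier: str | None     # tier of the winning records

    @property
    def prediction_only(self) -> bool:
        return self.tier == "PREDICTED"


class AnnotationStore:
    """In-memory information system for one submitted protein."""

    def __init__(self, seq_id: str, sequence: str):
        self.seq_id = seq_id
        self.sequence = sequence
        self._records: list[FeatureRecord] = []
        self._seen: set = set()
        self.warnings: list[str] = []

    def __len__(self) -> int:
        return len(self._records)

    @property
    def records(self) -> list:
        return list(self._records)

    def ingest(
        self,
        records: list[FeatureRecord],
        mappings: dict[str, ResidueMapping] | None = None,
    ) -> None:
        """Add records, re-numbering them onto the submitted sequence.

        ``mappings`` maps each record's ``seq_id`` to a ResidueMapping onto
        the submitted sequence; records already in submitted numbering
        (seq_id equal to the store's) use the identity mapping.  Records
        whose span maps entirely into gaps are dropped with a warning;
        partial overlaps are clipped to the mapped extent.  Ingest is
        idempotent: exact duplicates are skipped.
        """
        mappings = mappings or {}
        n = len(self.sequence)
        for rec in records:
            if rec.seq_id == self.seq_id and rec.seq_id not in mappings:
                mapped = rec
            else:
                mapping = mappings.get(rec.seq_id)
                if mapping is None:
                    raise KeyError(
                        f"no residue mapping for source sequence {rec.seq_id!r}"
                    )
                positions = [
                    p
                    for p in (
                        map_position(mapping, src)
                        for src in range(rec.begin, rec.end + 1)
                    )
                    if p is not None
                ]
                if not positions:
                    self.warnings.append(
                        f"{rec.feature_type} {rec.begin}-{rec.end} from "
                        f"{rec.seq_id}: span unmapped on the submitted "
                        "sequence; record dropped"
                    )
                    continue
                mapped = FeatureRecord(
                    seq_id=self.seq_id,
                    source_tier=rec.source_tier,
                    category=rec.category,
                    feature_type=rec.feature_type,
                    begin=min(positions),
                    end=max(positions),
                    value=rec.value,
                    partner=rec.partner,
                    description=rec.description,
                )
            if mapped.end > n:
                self.warnings.append(
                    f"{mapped.feature_type} {mapped.begin}-{mapped.end}: extends "
                    f"past the submitted sequence (length {n}); record dropped"
                )
                continue
            key = mapped.identity()
            if key in self._seen:
                continue
            self._seen.add(key)
            self._records.append(mapped)

    def query_residue(self, position: int) -> ResidueAnnotation:
        """All records overlapping a 1-based position, grouped by
        (category, feature_type)."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} outside sequence 1..{len(self.sequence)}"
            )
        ann = ResidueAnnotation(
            position=position, wild_type=self.sequence[position - 1]
        )
        for rec in self._records:
            if rec.covers(position):
                ann.groups.setdefault((rec.category, rec.feature_type), []).append(rec)
        return ann

    def dump(self) -> list:
        """Diff-stable ordering: (begin, category, tier, feature_type)."""
        return sorted(
            self._records,
            key=lambda r: (
                r.begin, r.category, _TIER_RANK[r.source_tier],
                r.feature_type, r.end, str(r.partner),
            ),
        )


def resolve(annotation: ResidueAnnotation, feature_type: str) -> Resolution:
    """Source-rank the records of one feature type at one residue.

    Returns the records of the single most reliable tier present; lower
    tiers are suppressed for conclusions but retained as corroboration.
    """
    recs = annotation.of_type(feature_type)
    if not recs:
        return Resolution(best=[], corroborating=[], tier=None)
    best_rank = min(_TIER_RANK[r.source_tier] for r in recs)
    tier = TIER_ORDER[best_rank]
    best = [r for r in recs if r.source_tier == tier]
    rest = [r for r in recs if r.source_tier != tier]
    return Resolution(best=best, corroborating=rest, tier=tier)
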