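"""Homology-based annotation transfer.

Hits are gated at E-value <= 1e-3 (the standard PSI-BLAST threshold), self
hits are excluded, and the localization of the best surviving hit — the one
with the highest percentage sequence identity, which slightly outperforms
taking the best E-value — is transferred to the query.  The reliability
index is a clamped linear function of PIDE saturating at 0 for PIDE <= 20
and reaching 100 at PIDE 100.
"""

from __future__ import annotations

from dataclasses import dataclass

from loctree.errors import ValidationError
from loctree.records import (
    AnnotationDB,
    BlastHit,
    Prediction,
    PredictionSource,
)

__all__ = [
    "TransferPolicy",
    "best_hit",
    "filter_hits",
    "predict_homology",
    "ri_from_pide",
]

PIDE_FLOOR_DEFAULT = 20.0
EVALUE_MAX_DEFAULT = 1e-3


@dataclass(frozen=True)
class TransferPolicy:
    """Filtering policy: E-value gate, RI saturation floor, self-hit rule."""

    evalue_max: float = EVALUE_MAX_DEFAULT
    pide_floor: float = PIDE_FLOOR_DEFAULT
    exclude_self: bool = True

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValidationError(f"evalue_max must be > 0, got {self.evalue_max}")
        if not 0.0 <= self.pide_floor < 100.0:
            raise ValidationError(
                f"pide_floor must be in [0,100), got {self.pide_floor}")


def filter_hits(hits: list[BlastHit], query_id: str, policy: TransferPolicy,
                db: AnnotationDB) -> list[BlastHit]:
    """Keep hits passing the E-value gate, non-self, with annotated subjects.

    Order-preserving and idempotent; an empty result is valid.
    """
    return [
        h for h in hits
        if h.evalue <= policy.evalue_max
        and not (policy.exclude_self and h.subject_id == query_id)
        and h.subject_id in db
    ]


def best_hit(hits: list[BlastHit]) -> BlastHit | None:
    """Hit with maximum PIDE; ties by lower E-value, then by input order."""
    best: BlastHit | None = None
    for h in hits:
        if best is None or h.pide > best.pide or (
            h.pide == best.pide and h.evalue < best.evalue
        ):
            best = h
    return best


def ri_from_pide(pide: float, pide_floor: float = PIDE_FLOOR_DEFAULT) -> int:
    """Reliability index of a transfer, from percentage identity.

    Linear from 0 at the saturation floor (PIDE <= 20) to 100 at PIDE 100:
    ``round(100 * (clamp(pide, floor, 100) - floor) / (100 - floor))``.
    """
    if not 0.0 <= pide <= 100.0:
        raise ValidationError(f"pide {pide} outside [0,100]")
    clamped = min(max(pide, pide_floor), 100.0)
    return int(round(100.0 * (clamped - pide_floor) / (100.0 - pide_floor)))


def predict_homology(query_id: str, hits: list[BlastHit], db: AnnotationDB,
                     policy: TransferPolicy = TransferPolicy()
                     ) -> Prediction | None:
    """Transfer the best surviving hit's class, or None when nothing survives."""
    surviving = filter_hits(hits, query_id, policy, db)
    top = best_hit(surviving)
    if top is None:
        return None
    loc_class = db.get(top.subject_id)
    if loc_class is None:  # filter guarantees membership; guard regardless
        raise ValidationError(
            f"{query_id}: surviving subject {top.subject_id!r} not annotated")
    return Prediction(
        id=query_id,
        loc_class=loc_class,
        ri=ri_from_pide(top.pide, policy.pide_floor),
        source=PredictionSource.HOMOLOGY,
        hit=top,
    )
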