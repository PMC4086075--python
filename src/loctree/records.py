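"""Shared domain records: sequences, profiles, hits, annotations, predictions."""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from loctree.classes import DomainOfLife, class_set
from loctree.errors import ValidationError

# the 20 standard amino acids in alphabetical one-letter order; the kernel
# alphabet.  'X' (unknown) is allowed in sequences but is not a kernel letter.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_INDEX = {a: i for i, a in enumerate(ALPHABET)}
SEQUENCE_ALPHABET = frozenset(ALPHABET + "X")

# profile probabilities are clamped to [PROB_FLOOR, 1]; scores are -ln(p), so
# the largest (least likely) representable score is SCORE_CEILING.
PROB_FLOOR = 1e-3
SCORE_CEILING = -math.log(PROB_FLOOR)  # ~6.9078

__all__ = [
    "ALPHABET",
    "ALPHABET_INDEX",
    "AnnotationDB",
    "BlastHit",
    "PROB_FLOOR",
    "Prediction",
    "PredictionSource",
    "ProfileSource",
    "SCORE_CEILING",
    "SequenceProfile",
    "SequenceRecord",
]


class ProfileSource(enum.Enum):
    PARSED_PSSM = "PARSED_PSSM"
    FABRICATED = "FABRICATED"


class PredictionSource(enum.Enum):
    HOMOLOGY = "HOMOLOGY"
    DE_NOVO = "DE_NOVO"


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence; residues over the 20 standard letters plus X."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record with empty id")
        if not self.residues:
            raise ValidationError(f"{self.id}: empty sequence")
        bad = set(self.residues) - SEQUENCE_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.id}: residues outside alphabet: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceProfile:
    """Per-position residue scoring matrix on a -ln(probability) scale.

    ``scores[i, j]`` is the cost of letter ``ALPHABET[j]`` at position ``i``;
    lower means more likely.  All scores lie in [0, SCORE_CEILING] and every
    position must prefer at least one letter strictly below the ceiling.
    """

    id: str
    scores: np.ndarray
    source: ProfileSource
    residues: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(ALPHABET):
            raise ValidationError(
                f"{self.id}: profile matrix must be L x {len(ALPHABET)}, "
                f"got {self.scores.shape}"
            )
        if self.scores.shape[0] == 0:
            raise ValidationError(f"{self.id}: zero-length profile")
        if not np.all(np.isfinite(self.scores)):
            raise ValidationError(f"{self.id}: non-finite profile scores")
        if not np.all(self.scores.min(axis=1) < SCORE_CEILING):
            raise ValidationError(
                f"{self.id}: profile row with no score below the clamp ceiling"
            )
        if self.residues is not None and len(self.residues) != self.scores.shape[0]:
            raise ValidationError(f"{self.id}: residue/profile length mismatch")

    @property
    def length(self) -> int:
        return int(self.scores.shape[0])


@dataclass(frozen=True)
class BlastHit:
    """One row of tabular (outfmt-6 style) hit output.

    Alignment coordinates are 1-based inclusive, the native convention of the
    format; ``pide`` is the percentage identity over the alignment.
    """

    query_id: str
    subject_id: str
    pide: float
    aln_length: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pide <= 100.0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: "
                                  f"pide {self.pide} outside [0,100]")
        if self.evalue < 0:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: "
                                  f"negative evalue {self.evalue}")
        if self.qstart > self.qend or self.sstart > self.send:
            raise ValidationError(f"hit {self.query_id}->{self.subject_id}: "
                                  "alignment start > end")


@dataclass
class AnnotationDB:
    """Protein id -> single localization class, for one domain of life."""

    entries: dict[str, str]
    domain_of_life: DomainOfLife

    def __post_init__(self) -> None:
        valid = set(class_set(self.domain_of_life))
        for pid, cls in self.entries.items():
            if cls not in valid:
                raise ValidationError(
                    f"{pid}: class {cls!r} not in the "
                    f"{self.domain_of_life.value} class set"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pid: str) -> bool:
        return pid in self.entries

    def __getitem__(self, pid: str) -> str:
        return self.entries[pid]

    def get(self, pid: str, default: str | None = None) -> str | None:
        return self.entries.get(pid, default)


@dataclass
class Prediction:
    """Per-protein output record.

    De novo predictions carry the SVM decision path (node id, side taken,
    step confidence); homology predictions carry the supporting hit instead.
    """

    id: str
    loc_class: str
    ri: int
    source: PredictionSource
    expected_accuracy: float | None = None
    go_terms: list[tuple[str, str]] = field(default_factory=list)
    path: list[tuple[str, str, float]] = field(default_factory=list)
    hit: BlastHit | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.ri <= 100:
            raise ValidationError(f"{self.id}: RI {self.ri} outside [0,100]")
        if self.source is PredictionSource.DE_NOVO:
            if self.hit is not None:
                raise ValidationError(f"{self.id}: de novo prediction with a hit")
            if not self.path:
                raise ValidationError(f"{self.id}: de novo prediction without path")
        else:
            if self.hit is None:
                raise ValidationError(f"{self.id}: homology prediction without hit")
            if self.path:
                raise ValidationError(f"{self.id}: homology prediction with a path")
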