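"""The combiner: homology transfer when a hit survives, SVM tree otherwise.

Also attaches GO terms for the predicted class and an expected accuracy
looked up from an RI calibration (a step function estimated on labeled
data — a fresh install has none until ``calibrate`` is run).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from loctree.classes import DomainOfLife
from loctree.errors import FormatError, ValidationError
from loctree.evaluation import ri_curve
from loctree.hierarchical import TreeModel, predict_de_novo
from loctree.homology import TransferPolicy, predict_homology
from loctree.io_formats import fabricate_profile
from loctree.records import (
    AnnotationDB,
    BlastHit,
    Prediction,
    PredictionSource,
    SequenceProfile,
    SequenceRecord,
)

__all__ = [
    "BatchResult",
    "GoMap",
    "RiCalibration",
    "attach_go",
    "calibrate",
    "default_go_map",
    "expected_accuracy",
    "load_calibration",
    "load_go_map",
    "predict",
    "predict_batch",
    "save_calibration",
]

logger = logging.getLogger(__name__)

_GO_ID_DIGITS = 7


@dataclass
class GoMap:
    """Localization class -> list of (GO term name, GO identifier)."""

    table: dict[str, list[tuple[str, str]]]

    def __post_init__(self) -> None:
        for cls, terms in self.table.items():
            for name, goid in terms:
                if not (goid.startswith("GO:") and len(goid) == 3 + _GO_ID_DIGITS
                        and goid[3:].isdigit()):
                    raise ValidationError(
                        f"{cls}: malformed GO identifier {goid!r}")

    def terms_for(self, loc_class: str) -> list[tuple[str, str]]:
        return list(self.table.get(loc_class, []))


@dataclass(frozen=True)
class RiCalibration:
    """Step-function RI -> expected accuracy, estimated on labeled data.

    ``bins`` are (ri_threshold, observed accuracy %) pairs with strictly
    increasing thresholds; a lookup returns the accuracy of the highest bin
    whose threshold does not exceed the RI.
    """

    domain_of_life: DomainOfLife
    bins: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValidationError("calibration with no bins")
        thresholds = [t for t, _ in self.bins]
        if thresholds != sorted(set(thresholds)):
            raise ValidationError("calibration thresholds must strictly increase")
        for _, acc in self.bins:
            if not 0.0 <= acc <= 100.0:
                raise ValidationError(f"calibration accuracy {acc} outside [0,100]")


def expected_accuracy(ri: int, calibration: RiCalibration) -> float:
    """Accuracy of the highest calibration bin with threshold <= ri."""
    if not 0 <= ri <= 100:
        raise ValidationError(f"RI {ri} outside [0,100]")
    chosen: float | None = None
    for threshold, acc in calibration.bins:
        if threshold <= ri:
            chosen = acc
    if chosen is None:  # ri below the lowest threshold: use the lowest bin
        chosen = calibration.bins[0][1]
    return chosen


def attach_go(prediction: Prediction, go_map: GoMap) -> Prediction:
    """Set GO terms from the map; unmapped classes get an empty list."""
    prediction.go_terms = go_map.terms_for(prediction.loc_class)
    return prediction


def predict(query: SequenceRecord,
            profile: SequenceProfile | None,
            hits: Sequence[BlastHit] | None,
            model: TreeModel | None,
            db: AnnotationDB | None,
            policy: TransferPolicy = TransferPolicy(),
            go_map: GoMap | None = None,
            calibration: RiCalibration | None = None) -> Prediction:
    """One query through the combined predictor.

    Homology transfer is attempted first (needs hits + an annotation db);
    if nothing survives filtering, the SVM tree predicts de novo from the
    profile, fabricating one from the sequence when none is supplied.
    """
    result: Prediction | None = None
    if hits is not None and db is not None:
        result = predict_homology(query.id, list(hits), db, policy)
    if result is None:
        if model is None:
            raise ValidationError(
                f"{query.id}: no surviving hit and no model for de novo")
        if profile is None:
            profile = fabricate_profile(query)
        result = predict_de_novo(profile, model)
    if go_map is not None:
        attach_go(result, go_map)
    if calibration is not None:
        result.expected_accuracy = expected_accuracy(result.ri, calibration)
    return result


@dataclass
class BatchResult:
    predictions: list[Prediction]
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def homology_fraction(self) -> float:
        if not self.predictions:
            return 0.0
        n_hom = sum(1 for p in self.predictions
                    if p.source is PredictionSource.HOMOLOGY)
        return n_hom / len(self.predictions)


def predict_batch(queries: Iterable[SequenceRecord],
                  profiles: Mapping[str, SequenceProfile] | None,
                  hits_by_query: Mapping[str, Sequence[BlastHit]] | None,
                  model: TreeModel | None,
                  db: AnnotationDB | None,
                  policy: TransferPolicy = TransferPolicy(),
                  go_map: GoMap | None = None,
                  calibration: RiCalibration | None = None) -> BatchResult:
    """Stream queries through :func:`predict`; per-query failures are logged
    and collected, not fatal."""
    result = BatchResult(predictions=[])
    for query in queries:
        try:
            result.predictions.append(predict(
                query,
                profiles.get(query.id) if profiles else None,
                hits_by_query.get(query.id, []) if hits_by_query is not None else None,
                model, db, policy, go_map, calibration,
            ))
        except (ValidationError, FormatError) as exc:
            logger.warning("query %s failed: %s", query.id, exc)
            result.failures.append((query.id, str(exc)))
    return result


def calibrate(predictions: Sequence[Prediction], truth: AnnotationDB,
              domain: DomainOfLife,
              thresholds: Sequence[int] = tuple(range(0, 101, 10))
              ) -> RiCalibration:
    """Estimate the RI -> accuracy step function from labeled predictions."""
    curve = ri_curve(predictions, truth, thresholds)
    bins = tuple((t, acc) for t, acc, _ in curve if acc is not None)
    if not bins:
        raise ValidationError("no populated RI bins to calibrate from")
    return RiCalibration(domain, bins)


# ---------------------------------------------------------------------------
# config file IO

def load_go_map(path: str | os.PathLike) -> GoMap:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    return GoMap({cls: [(n, g) for n, g in terms]
                  for cls, terms in payload.items()})


def default_go_map() -> GoMap:
    """The shipped one-term-per-class GO mapping (editable config data)."""
    ref = resources.files("loctree.data") / "go_map.json"
    payload = json.loads(ref.read_text())
    return GoMap({cls: [(n, g) for n, g in terms]
                  for cls, terms in payload.items()})


def save_calibration(calibration: RiCalibration, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump({
            "domain": calibration.domain_of_life.value,
            "bins": [[t, a] for t, a in calibration.bins],
        }, fh)


def load_calibration(path: str | os.PathLike) -> RiCalibration:
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    return RiCalibration(
        DomainOfLife.from_string(payload["domain"]),
        tuple((int(t), float(a)) for t, a in payload["bins"]),
    )
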