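"""Performance statistics: per-class Acc/Cov, n-state accuracy Qn, bootstrap
standard errors, and RI-accuracy-coverage curves.

Definitions, per localization class L:

    Acc(L) = 100 * TP / (TP + FP)        (precision)
    Cov(L) = 100 * TP / (TP + FN)        (recall)
    Qn     = 100 * #correct / #observed  (n-state accuracy)

Standard errors come from a subsampling bootstrap: draw ``n_sets`` (default
1000) subsets of ceil(15% of N) proteins *without replacement*; each draw's
metric x_i is compared against the full-set metric <x> (not the bootstrap
mean), sigma = sqrt(sum (x_i - <x>)^2 / n), SE = sigma / sqrt(n - 1).

Random-draw contract (so an independent re-implementation can reproduce the
draws exactly): with predictions indexed 0..N-1 in list order, a single
``numpy.random.default_rng(seed)`` generator draws, for set i = 1..n_sets in
order, ``rng.choice(N, size=m, replace=False)`` — one call per set, nothing
else consumes the stream.

Metrics that are undefined on a subset (empty, or zero denominator) are
skipped and counted, never imputed; undefined Acc/Cov are reported as None
("n/a" in rendered reports), never 0 or 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from loctree.errors import ValidationError
from loctree.records import AnnotationDB, Prediction

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "EvalCounts",
    "EvalReport",
    "accuracy",
    "bootstrap_se",
    "confusion",
    "coverage",
    "evaluate",
    "qn",
    "ri_curve",
]

MergeMap = dict[str, str]


@dataclass
class EvalCounts:
    """Per-class TP/FP/FN triples."""

    per_class: dict[str, tuple[int, int, int]]

    def tp(self, cls: str) -> int:
        return self.per_class.get(cls, (0, 0, 0))[0]

    def fp(self, cls: str) -> int:
        return self.per_class.get(cls, (0, 0, 0))[1]

    def fn(self, cls: str) -> int:
        return self.per_class.get(cls, (0, 0, 0))[2]


@dataclass(frozen=True)
class BootstrapConfig:
    """Subsampling-bootstrap settings; sampling is always without replacement."""

    n_sets: int = 1000
    fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sets < 2:
            raise ValidationError(f"n_sets must be >= 2, got {self.n_sets}")
        if not 0.0 < self.fraction < 1.0:
            raise ValidationError(f"fraction must be in (0,1), got {self.fraction}")


@dataclass(frozen=True)
class BootstrapResult:
    se: float
    sigma: float
    n_used: int
    n_skipped: int


@dataclass
class EvalReport:
    """Full evaluation summary for one prediction set."""

    n_states: int
    qn: float
    se: float | None
    per_class: dict[str, dict[str, float | int | None]]
    ri_curve: list[tuple[int, float | None, float]] = field(default_factory=list)


def _merged(label: str, merge: MergeMap | None) -> str:
    return merge.get(label, label) if merge else label


def confusion(predictions: Sequence[Prediction], truth: AnnotationDB,
              merge: MergeMap | None = None) -> EvalCounts:
    """Per-class TP/FP/FN after applying *merge* to both labels."""
    tp: dict[str, int] = {}
    fp: dict[str, int] = {}
    fn: dict[str, int] = {}
    for p in predictions:
        if p.id not in truth:
            raise ValidationError(f"{p.id}: predicted protein missing from truth")
        predicted = _merged(p.loc_class, merge)
        observed = _merged(truth[p.id], merge)
        if predicted == observed:
            tp[predicted] = tp.get(predicted, 0) + 1
        else:
            fp[predicted] = fp.get(predicted, 0) + 1
            fn[observed] = fn.get(observed, 0) + 1
    classes = set(tp) | set(fp) | set(fn)
    return EvalCounts({
        c: (tp.get(c, 0), fp.get(c, 0), fn.get(c, 0)) for c in classes
    })


def accuracy(counts: EvalCounts, cls: str) -> float | None:
    """Acc(L) = 100 TP / (TP + FP); None when the class was never predicted."""
    tp, fp, _ = counts.per_class.get(cls, (0, 0, 0))
    if tp + fp == 0:
        return None
    return 100.0 * tp / (tp + fp)


def coverage(counts: EvalCounts, cls: str) -> float | None:
    """Cov(L) = 100 TP / (TP + FN); None when the class was never observed."""
    tp, _, fn = counts.per_class.get(cls, (0, 0, 0))
    if tp + fn == 0:
        return None
    return 100.0 * tp / (tp + fn)


def qn(predictions: Sequence[Prediction], truth: AnnotationDB,
       merge: MergeMap | None = None) -> float:
    """n-state accuracy over the evaluated predictions."""
    if not predictions:
        raise ValidationError("Qn undefined on an empty prediction set")
    correct = 0
    for p in predictions:
        if p.id not in truth:
            raise ValidationError(f"{p.id}: predicted protein missing from truth")
        if _merged(p.loc_class, merge) == _merged(truth[p.id], merge):
            correct += 1
    return 100.0 * correct / len(predictions)


def n_states(truth: AnnotationDB, merge: MergeMap | None = None) -> int:
    return len({_merged(c, merge) for c in truth.entries.values()})


def bootstrap_se(predictions: Sequence[Prediction], truth: AnnotationDB,
                 metric: Callable[[Sequence[Prediction], AnnotationDB], float | None],
                 config: BootstrapConfig = BootstrapConfig()) -> BootstrapResult:
    """Subsampling-bootstrap standard error of *metric*.

    See the module docstring for the draw contract.  ``<x>`` is the metric on
    the full set; draws on which the metric is undefined (returns None or
    raises ValidationError) are skipped and counted.
    """
    n = len(predictions)
    m = math.ceil(config.fraction * n)
    if m < 1:
        raise ValidationError("resample size is zero")
    full = metric(predictions, truth)
    if full is None:
        raise ValidationError("metric undefined on the full set")
    rng = np.random.default_rng(config.seed)
    deviations: list[float] = []
    skipped = 0
    for _ in range(config.n_sets):
        idx = rng.choice(n, size=m, replace=False)
        subset = [predictions[i] for i in idx]
        try:
            x_i = metric(subset, truth)
        except ValidationError:
            x_i = None
        if x_i is None:
            skipped += 1
            continue
        deviations.append(x_i - full)
    n_used = len(deviations)
    if n_used == 0:
        raise ValidationError("metric undefined on every bootstrap set")
    dev = np.asarray(deviations)
    sigma = float(np.sqrt(np.sum(dev ** 2) / n_used))
    se = sigma if n_used == 1 else sigma / math.sqrt(n_used - 1)
    return BootstrapResult(se=se, sigma=sigma, n_used=n_used, n_skipped=skipped)


def ri_curve(predictions: Sequence[Prediction], truth: AnnotationDB,
             thresholds: Iterable[int] = range(0, 101),
             merge: MergeMap | None = None
             ) -> list[tuple[int, float | None, float]]:
    """(threshold, accuracy above threshold, coverage) along the RI scale.

    Coverage at threshold t is the percentage of predictions with RI >= t;
    accuracy is Qn restricted to that subset (None when it is empty).
    """
    if not predictions:
        raise ValidationError("RI curve undefined on an empty prediction set")
    total = len(predictions)
    curve: list[tuple[int, float | None, float]] = []
    for t in thresholds:
        subset = [p for p in predictions if p.ri >= t]
        cov = 100.0 * len(subset) / total
        acc = qn(subset, truth, merge) if subset else None
        curve.append((int(t), acc, cov))
    return curve


def evaluate(predictions: Sequence[Prediction], truth: AnnotationDB,
             merge: MergeMap | None = None,
             bootstrap: BootstrapConfig | None = None,
             with_ri_curve: bool = True) -> EvalReport:
    """One-stop report: Qn (+SE), per-class Acc/Cov, RI curve."""
    counts = confusion(predictions, truth, merge)
    overall = qn(predictions, truth, merge)
    se = None
    if bootstrap is not None:
        se = bootstrap_se(
            predictions, truth,
            lambda preds, db: qn(preds, db, merge) if preds else None,
            bootstrap,
        ).se
    per_class: dict[str, dict[str, float | int | None]] = {}
    for cls in sorted(counts.per_class):
        tp, fp, fn = counts.per_class[cls]
        per_class[cls] = {
            "tp": tp, "fp": fp, "fn": fn,
            "acc": accuracy(counts, cls),
            "cov": coverage(counts, cls),
        }
    observed = {_merged(truth[p.id], merge) for p in predictions}
    return EvalReport(
        n_states=len(observed),
        qn=overall,
        se=se,
        per_class=per_class,
        ri_curve=(ri_curve(predictions, truth, merge=merge)
                  if with_ri_curve else []),
    )
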