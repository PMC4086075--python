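import math

import numpy as np
import pytest

from loctree.classes import DomainOfLife
from loctree.errors import ValidationError
from loctree.evaluation import (
    BootstrapConfig,
    accuracy,
    bootstrap_se,
    confusion,
    coverage,
    evaluate,
    qn,
    ri_curve,
)
from loctree.records import AnnotationDB, BlastHit, Prediction, PredictionSource


def _pred(pid, cls, ri=50):
    return Prediction(pid, cls, ri, PredictionSource.HOMOLOGY,
                      hit=BlastHit(pid, "s", 60.0, 10, 4, 0, 1, 10, 1, 10,
                                   1e-9, 20.0))


def _db(mapping, domain=DomainOfLife.ARCHAEA):
    return AnnotationDB(mapping, domain)


class TestConfusion:
    def test_perfect_two_class(self):
        truth = _db({f"a{i}": "cytosol" for i in range(5)}
                    | {f"b{i}": "extra-cellular" for i in range(5)})
        preds = [_pred(pid, cls) for pid, cls in truth.entries.items()]
        counts = confusion(preds, truth)
        for cls in ("cytosol", "extra-cellular"):
            assert counts.per_class[cls] == (5, 0, 0)

    def test_everything_predicted_one_class(self):
        truth = _db({f"a{i}": "cytosol" for i in range(5)}
                    | {f"b{i}": "extra-cellular" for i in range(5)})
        preds = [_pred(pid, "cytosol") for pid in truth.entries]
        counts = confusion(preds, truth)
        assert counts.per_class["cytosol"] == (5, 5, 0)
        assert counts.per_class["extra-cellular"] == (0, 0, 5)

    def test_merge_turns_cross_prediction_into_tp(self):
        truth = _db({"p": "nucleus"}, DomainOfLife.EUKARYOTA)
        preds = [_pred("p", "nucleus membrane")]
        merge = {"nucleus membrane": "nucleus"}
        counts = confusion(preds, truth, merge)
        assert counts.per_class["nucleus"] == (1, 0, 0)

    def test_missing_truth_rejected(self):
        truth = _db({"a": "cytosol"})
        with pytest.raises(ValidationError):
            confusion([_pred("zzz", "cytosol")], truth)


class TestAccCov:
    def _counts(self, tp, fp, fn):
        from loctree.evaluation import EvalCounts
        return EvalCounts({"cytosol": (tp, fp, fn)})

    @pytest.mark.parametrize("tp,fp,expected", [
        (9, 1, 90.0), (5, 5, 50.0), (10, 0, 100.0),
    ])
    def test_accuracy_arithmetic(self, tp, fp, expected):
        assert accuracy(self._counts(tp, fp, 0), "cytosol") == expected

    @pytest.mark.parametrize("tp,fn,expected", [
        (9, 1, 90.0), (0, 10, 0.0), (10, 0, 100.0),
    ])
    def test_coverage_arithmetic(self, tp, fn, expected):
        assert coverage(self._counts(tp, 0, fn), "cytosol") == expected

    def test_zero_denominator_is_undefined_not_zero(self):
        assert accuracy(self._counts(0, 0, 3), "cytosol") is None
        assert coverage(self._counts(0, 0, 0), "cytosol") is None


class TestQn:
    def test_fraction_correct(self):
        truth = _db({f"p{i}": "cytosol" for i in range(10)})
        preds = [_pred(f"p{i}", "cytosol" if i < 8 else "extra-cellular")
                 for i in range(10)]
        assert qn(preds, truth) == 80.0

    def test_all_correct(self):
        truth = _db({"p": "cytosol"})
        assert qn([_pred("p", "cytosol")], truth) == 100.0

    def test_merging_cross_predicted_classes_raises_qn(self):
        # two classes systematically confused with each other: Qn 50 -> 100
        truth = _db({"a1": "cytosol", "a2": "plasma membrane",
                     "b1": "cytosol", "b2": "plasma membrane"})
        preds = [_pred("a1", "plasma membrane"), _pred("a2", "cytosol"),
                 _pred("b1", "cytosol"), _pred("b2", "plasma membrane")]
        assert qn(preds, truth) == 50.0
        merge = {"plasma membrane": "cytosol"}
        assert qn(preds, truth, merge) == 100.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            qn([], _db({"p": "cytosol"}))


class TestBootstrap:
    def _toy(self, n_errors=2, n=20):
        truth = _db({f"p{i}": "cytosol" for i in range(n)})
        preds = [_pred(f"p{i}",
                       "extra-cellular" if i < n_errors else "cytosol")
                 for i in range(n)]
        return preds, truth

    def test_all_correct_gives_exactly_zero(self):
        preds, truth = self._toy(n_errors=0)
        res = bootstrap_se(preds, truth, qn,
                           BootstrapConfig(n_sets=50, seed=1))
        assert res.se == 0.0 and res.sigma == 0.0

    def test_two_sets_se_equals_sigma(self):
        preds, truth = self._toy()
        res = bootstrap_se(preds, truth, qn,
                           BootstrapConfig(n_sets=2, seed=3))
        assert res.se == res.sigma

    def test_dual_implementation_oracle(self):
        """Independent re-implementation of the documented draw contract:
        one default_rng(seed), one choice(N, size=m, replace=False) per set,
        metric re-derived by direct counting."""
        preds, truth = self._toy(n_errors=2, n=20)
        config = BootstrapConfig(n_sets=200, fraction=0.15, seed=7)
        res = bootstrap_se(preds, truth, qn, config)

        correct = np.array([p.loc_class == truth[p.id] for p in preds])
        full = 100.0 * correct.mean()
        m = math.ceil(config.fraction * len(preds))
        rng = np.random.default_rng(config.seed)
        sq_dev = []
        for _ in range(config.n_sets):
            idx = rng.choice(len(preds), size=m, replace=False)
            x_i = 100.0 * correct[idx].mean()
            sq_dev.append((x_i - full) ** 2)
        sigma = math.sqrt(sum(sq_dev) / config.n_sets)
        se = sigma / math.sqrt(config.n_sets - 1)
        assert abs(res.sigma - sigma) < 1e-12
        assert abs(res.se - se) < 1e-12

    def test_undefined_resamples_skipped_and_counted(self):
        preds, truth = self._toy()
        calls = {"n": 0}

        def flaky_metric(subset, db):
            if len(subset) == len(preds):
                return qn(subset, db)
            calls["n"] += 1
            return None if calls["n"] % 2 else qn(subset, db)

        res = bootstrap_se(preds, truth, flaky_metric,
                           BootstrapConfig(n_sets=10, seed=5))
        assert res.n_skipped == 5 and res.n_used == 5


class TestRiCurve:
    def _mixed(self):
        truth = _db({f"p{i}": "cytosol" for i in range(10)})
        preds = [_pred(f"p{i}", "cytosol" if i % 2 else "extra-cellular",
                       ri=10 * i) for i in range(10)]
        return preds, truth

    def test_threshold_zero_is_full_set(self):
        preds, truth = self._mixed()
        curve = ri_curve(preds, truth)
        t0, acc0, cov0 = curve[0]
        assert t0 == 0 and cov0 == 100.0
        assert acc0 == pytest.approx(qn(preds, truth))

    def test_above_maximum_ri_empty(self):
        preds, truth = self._mixed()
        curve = dict((t, (a, c)) for t, a, c in ri_curve(preds, truth))
        acc, cov = curve[100]
        assert acc is None and cov == 0.0

    def test_coverage_non_increasing(self):
        rng = np.random.default_rng(21)
        truth = _db({f"p{i}": "cytosol" for i in range(30)})
        preds = [_pred(f"p{i}", "cytosol", ri=int(rng.integers(0, 101)))
                 for i in range(30)]
        covs = [c for _, _, c in ri_curve(preds, truth)]
        assert all(b <= a for a, b in zip(covs, covs[1:]))
        # direct-count oracle at each threshold
        ris = [p.ri for p in preds]
        for t, _, c in ri_curve(preds, truth):
            assert c == pytest.approx(100.0 * sum(r >= t for r in ris) / 30)


class TestEvaluateReport:
    def test_report_consistency(self):
        truth = _db({f"p{i}": ("cytosol" if i < 6 else "extra-cellular")
                     for i in range(10)})
        preds = [_pred(f"p{i}", "cytosol" if i < 8 else "extra-cellular")
                 for i in range(10)]
        report = evaluate(preds, truth, bootstrap=BootstrapConfig(n_sets=50, seed=2))
        assert report.qn == 80.0
        assert report.n_states == 2
        # micro consistency: sum of per-class TP equals the Qn numerator
        tp_sum = sum(row["tp"] for row in report.per_class.values())
        assert tp_sum == 8
        assert report.se is not None and report.se >= 0
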