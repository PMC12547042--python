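"""Metric oracles: hand-counted confusion matrices, brute-force pairwise
concordance, hand product-limit computations, and an independent IPCW Brier
implementation from scikit-survival."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msprog.eval_metrics import (
    classification_report,
    concordance_index,
    integrated_brier_score,
    kaplan_meier,
)


def labels_from_confusion(cm):
    """Expand a confusion matrix into (true, predicted) label vectors."""
    classes = ["C1", "C2", "C3"]
    yt, yp = [], []
    for i in range(3):
        for j in range(3):
            yt += [classes[i]] * cm[i][j]
            yp += [classes[j]] * cm[i][j]
    return yt, yp


def cindex_bruteforce(times, events, risks):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den


class TestClassificationReport:
    def test_perfect_predictions(self):
        yt = ["C1"] * 5 + ["C2"] * 7 + ["C3"] * 4
        rep = classification_report(yt, yt, n_boot=50)
        for key in ("accuracy", "precision", "recall", "f1"):
            assert rep[key] == pytest.approx(1.0)
        for c in ("C1", "C2", "C3"):
            assert rep["per_class"][c]["specificity"] == pytest.approx(1.0)

    def test_hand_counted_matrix(self):
        yt, yp = labels_from_confusion([[5, 1, 0], [1, 8, 1], [0, 1, 3]])
        rep = classification_report(yt, yp, n_boot=50)
        assert rep["accuracy"] == pytest.approx(16 / 20)
        assert rep["per_class"]["C1"]["sensitivity"] == pytest.approx(5 / 6)
        # specificity of C1: 13 of 14 non-C1 patients not predicted C1
        assert rep["per_class"]["C1"]["specificity"] == pytest.approx(13 / 14)

    def test_bootstrap_ci_brackets_estimate_and_tightens_with_n(self):
        rng = np.random.default_rng(0)
        widths = {}
        for n in (100, 1000):
            yt = np.array(["C1", "C2", "C3"])[rng.choice(3, n, p=[0.2, 0.5, 0.3])]
            yp = np.where(rng.random(n) < 0.7, yt, "C2")
            rep = classification_report(yt, yp, n_boot=400, seed=1)
            lo, hi = rep["ci95"]["accuracy"]
            assert lo <= rep["accuracy"] <= hi
            widths[n] = hi - lo
        assert widths[1000] < widths[100]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classification_report([], [], n_boot=10)


class TestConcordance:
    def test_worked_example_perfect_ordering(self):
        assert concordance_index([2, 4, 5], [1, 1, 0], [0.9, 0.5, 0.1]) == pytest.approx(1.0)

    def test_reversed_ordering_scores_zero(self):
        assert concordance_index([2, 4, 5], [1, 1, 0], [0.1, 0.5, 0.9]) == pytest.approx(0.0)

    def test_all_tied_risks_score_half(self):
        assert concordance_index([2, 4, 5], [1, 1, 0], [0.3, 0.3, 0.3]) == pytest.approx(0.5)

    def test_censored_shorter_time_is_not_comparable(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], [0, 1], [0.5, 0.1])

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines.utils import concordance_index as ll_cindex

        rng = np.random.default_rng(9)
        t = rng.exponential(10, 80)  # continuous draws: no tied times
        e = rng.integers(0, 2, 80)
        e[:5] = 1
        r = rng.standard_normal(80)
        assert concordance_index(t, e, r) == pytest.approx(float(ll_cindex(t, -r, e)))

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            t = np.round(rng.exponential(10, n), 1)
            e = rng.integers(0, 2, n)
            r = np.round(rng.standard_normal(n), 2)
            if not any(e[i] and (t[i] < t).any() for i in range(n)):
                continue
            assert concordance_index(t, e, r) == pytest.approx(cindex_bruteforce(t, e, r))


class TestKaplanMeier:
    def test_two_events(self):
        km = kaplan_meier([1.0, 2.0], [1, 1])
        assert km(1.0) == pytest.approx(0.5)
        assert km(2.0) == pytest.approx(0.0)

    def test_hand_product_limit_with_censoring(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
        assert km(1.0) == pytest.approx(2 / 3)
        assert km(2.5) == pytest.approx(2 / 3)
        assert km(3.0) == pytest.approx(0.0)

    def test_all_censored_stays_at_one(self):
        km = kaplan_meier([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(km(np.array([0.5, 1.5, 3.0])) == 1.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([-1.0, 2.0], [1, 1])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.1, 50), min_size=2, max_size=40), st.randoms(use_true_random=False))
    def test_no_censoring_equals_empirical_survival(self, times, _):
        times = np.round(np.asarray(times), 3)
        km = kaplan_meier(times, np.ones(len(times), dtype=int))
        for t in times:
            assert km(t) == pytest.approx((times > t).mean(), abs=1e-9)


class TestBrier:
    def test_perfect_predictions_score_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        grid = np.array([0.5, 1.5, 2.5, 3.5])
        S = (t[:, None] > grid[None, :]).astype(float)
        assert integrated_brier_score(S, t, e, grid) == pytest.approx(0.0)

    def test_constant_half_prediction_scores_quarter(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.ones(4, dtype=int)
        grid = np.array([0.5, 1.5, 2.5, 3.5])
        S = np.full((4, 4), 0.5)
        assert integrated_brier_score(S, t, e, grid) == pytest.approx(0.25)

    def test_grid_refinement_changes_little_on_smooth_case(self):
        rng = np.random.default_rng(3)
        n = 400
        t = rng.exponential(10, n)
        e = np.ones(n, dtype=int)
        lam = 0.1

        def surv(grid):
            return np.tile(np.exp(-lam * grid), (n, 1))

        coarse = np.linspace(1, 20, 100)
        fine = np.linspace(1, 20, 1000)
        assert integrated_brier_score(surv(coarse), t, e, coarse) == pytest.approx(
            integrated_brier_score(surv(fine), t, e, fine), abs=1e-3
        )

    def test_matches_scikit_survival_under_censoring(self):
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        from sksurv.util import Surv

        rng = np.random.default_rng(4)
        n = 300
        t = rng.exponential(10, n)
        c = rng.exponential(25, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        grid = np.linspace(np.quantile(time, 0.1), np.quantile(time, 0.8), 30)
        S = np.exp(-0.08 * np.tile(grid, (n, 1)) * rng.uniform(0.5, 2.0, (n, 1)))
        y = Surv.from_arrays(event.astype(bool), time)
        expected = sksurv_metrics.integrated_brier_score(y, y, S, grid)
        assert integrated_brier_score(S, time, event, grid) == pytest.approx(expected, rel=1e-6)
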