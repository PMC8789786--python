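"""ROC construction, AUC identities and cutoff selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hyokin import (
    DegenerateDataError,
    auc,
    evaluate_cutoff,
    roc_curve,
    run_roc_battery,
    select_cutoff,
)
from hyokin.roc import battery_table


def concordance_auc(values, labels, orientation="lower_positive"):
    """Brute-force pairwise oracle: P(pos on the positive side) + ties/2."""
    pos = [v for v, l in zip(values, labels) if l]
    neg = [v for v, l in zip(values, labels) if not l]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        if p == n:
            total += 0.5
        elif (p < n) == (orientation == "lower_positive"):
            total += 1.0
    return total / (len(pos) * len(neg))


def random_fixture(rng, n=30, ties=False):
    values = rng.normal(size=n)
    if ties:
        values = np.round(values, 1)
    labels = np.concatenate([np.ones(n // 2, bool), np.zeros(n - n // 2, bool)])
    rng.shuffle(labels)
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    return values, labels


class TestCurve:
    def test_perfect_separation(self):
        curve = roc_curve([1, 2, 3, 4], [True, True, False, False])
        assert auc([1, 2, 3, 4], [True, True, False, False]) == 1.0
        # passes through the ideal corner (fpr 0, tpr 1)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))

    def test_endpoints_and_monotonicity(self, rng):
        for ties in (False, True):
            values, labels = random_fixture(rng, 40, ties)
            curve = roc_curve(values, labels)
            assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
            assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
            assert np.all(np.diff(curve.fpr) >= 0)
            assert np.all(np.diff(curve.tpr) >= 0)

    def test_matches_brute_force_threshold_sweep(self, rng):
        values, labels = random_fixture(rng, 20, ties=True)
        curve = roc_curve(values, labels)
        for thr, fpr, tpr in zip(curve.thresholds, curve.fpr, curve.tpr):
            pred = values <= thr
            assert tpr == pytest.approx(pred[labels].mean())
            assert fpr == pytest.approx(pred[~labels].mean())

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            roc_curve([1, 2, 3], [True, True, True])


class TestAUC:
    def test_interleaved_example(self):
        # positives {1,3}, negatives {2,4}: 3 of 4 pairs concordant
        assert auc([1, 3, 2, 4], [True, True, False, False]) == pytest.approx(0.75)

    def test_orientation_flip(self, rng):
        values, labels = random_fixture(rng, 25, ties=True)
        a_lo = auc(values, labels, "lower_positive")
        a_hi = auc(values, labels, "higher_positive")
        assert a_lo + a_hi == pytest.approx(1.0, abs=1e-12)

    def test_equals_pairwise_concordance(self, rng):
        for n in (6, 17, 50):
            for ties in (False, True):
                values, labels = random_fixture(rng, n, ties)
                expected = concordance_auc(values, labels)
                assert abs(auc(values, labels) - expected) < 1e-12

    def test_matches_sklearn_on_negated_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        values, labels = random_fixture(rng, 40, ties=True)
        ours = auc(values, labels, "lower_positive")
        ref = roc_auc_score(labels.astype(int), -values)
        assert ours == pytest.approx(float(ref), abs=1e-12)

    def test_null_case(self, rng):
        values = rng.normal(size=2000)
        labels = np.arange(2000) % 2 == 0
        assert auc(values, labels) == pytest.approx(0.5, abs=0.05)


class TestCutoff:
    def test_perfect_separation_youden(self):
        curve = roc_curve([1, 2, 3, 4], [True, True, False, False])
        cut = select_cutoff(curve)
        assert cut.youden_j == pytest.approx(1.0)
        assert cut.sensitivity == 1.0 and cut.specificity == 1.0
        assert cut.cutoff == pytest.approx(2.5)  # midpoint threshold

    def test_degenerate_identical_values(self):
        curve = roc_curve([2, 2, 2, 2], [True, False, True, False])
        cut = select_cutoff(curve)
        assert cut.youden_j == pytest.approx(0.0)

    def test_matches_exhaustive_j_maximization(self, rng):
        values, labels = random_fixture(rng, 30, ties=True)
        curve = roc_curve(values, labels)
        cut = select_cutoff(curve)
        best_j = max(
            evaluate_cutoff(values, labels, thr)[0]
            + evaluate_cutoff(values, labels, thr)[1] - 1.0
            for thr in curve.thresholds[np.isfinite(curve.thresholds)]
        )
        assert cut.youden_j == pytest.approx(max(best_j, 0.0), abs=1e-12)

    def test_tie_break_prefers_sensitivity(self):
        # two thresholds reach J = 0.5; the higher-sensitivity one wins
        values = [1.0, 2.0, 3.0, 4.0]
        labels = [True, False, True, False]
        cut = select_cutoff(roc_curve(values, labels))
        assert cut.sensitivity == 1.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        seed=st.integers(0, 1000),
    )
    def test_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        values, labels = random_fixture(rng, 16, ties=True)
        c0 = select_cutoff(roc_curve(values, labels))
        c1 = select_cutoff(roc_curve(values + shift, labels))
        assert auc(values, labels) == pytest.approx(
            auc(values + shift, labels), abs=1e-12
        )
        assert c1.sensitivity == c0.sensitivity
        assert c1.specificity == c0.specificity
        if np.isfinite(c0.cutoff):
            assert c1.cutoff == pytest.approx(c0.cutoff + shift, abs=1e-6)


class TestEvaluateCutoff:
    def test_counting(self):
        sens, spec = evaluate_cutoff([1, 2, 3, 4], [True, True, False, False], 2.5)
        assert (sens, spec) == (1.0, 1.0)

    def test_cutoff_below_min(self):
        sens, spec = evaluate_cutoff([1, 2, 3, 4], [True, True, False, False], 0.0)
        assert (sens, spec) == (0.0, 1.0)

    def test_ties_count_as_positive(self):
        sens, _ = evaluate_cutoff([2.0, 3.0], [True, False], 2.0)
        assert sens == 1.0

    def test_matches_direct_counting(self, rng):
        values, labels = random_fixture(rng, 25, ties=True)
        cutoff = float(np.median(values))
        sens, spec = evaluate_cutoff(values, labels, cutoff)
        assert sens == (values[labels] <= cutoff).mean()
        assert spec == (values[~labels] > cutoff).mean()


class TestBattery:
    @staticmethod
    def table(rng):
        rows = []
        for group, n, shift in [("normal", 40, 0.0), ("aspiration", 20, -8.0),
                                ("stasis", 25, -3.0), ("unclassified", 5, 0.0)]:
            for _ in range(n):
                base = rng.normal(20 + shift, 2)
                rows.append({
                    "group": group, "Dx": base, "Dy": rng.normal(20, 2),
                    "Dxy": base + 10, "Vx": base, "Vy": rng.normal(25, 2),
                    "Vxy": base + 8,
                })
        return pd.DataFrame(rows)

    def test_layout_and_flags(self, rng):
        results = run_roc_battery(self.table(rng), target="aspiration")
        frame = battery_table(results)
        assert list(frame["Measure"]) == ["Dx", "Dy", "Dxy", "Vx", "Vy", "Vxy"]
        assert {"cutoff", "AUC", "sensitivity", "specificity", "acceptable"} <= set(
            frame.columns
        )
        by_param = dict(zip(frame["Measure"], frame["AUC"]))
        assert by_param["Dx"] > 0.7 and by_param["Dy"] < 0.7
        assert all(frame["AUC"].between(0, 1))

    def test_unclassified_never_enter(self, rng):
        table = self.table(rng)
        results = run_roc_battery(table, target="aspiration", comparator="rest")
        n_pos = (table["group"] == "aspiration").sum()
        n_neg = table["group"].isin(["normal", "stasis"]).sum()
        # curve tpr/fpr denominators reflect only classified recordings
        curve = results[0].curve
        assert curve.tpr[-1] == 1.0 and curve.fpr[-1] == 1.0
        sens, spec = evaluate_cutoff(
            pd.concat([
                table.loc[table.group == "aspiration", "Dx"],
                table.loc[table.group.isin(["normal", "stasis"]), "Dx"],
            ]).to_numpy(),
            np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)]),
            results[0].cutoff,
        )
        assert sens == pytest.approx(results[0].sensitivity)
        assert spec == pytest.approx(results[0].specificity)

    def test_normal_only_comparator(self, rng):
        table = self.table(rng)
        rest = run_roc_battery(table, target="aspiration", comparator="rest")
        normal_only = run_roc_battery(
            table, target="aspiration", comparator="normal_only"
        )
        assert normal_only[0].auc >= rest[0].auc  # stasis overlaps aspiration

    def test_absent_target_rejected(self, rng):
        table = self.table(rng)
        with pytest.raises(DegenerateDataError):
            run_roc_battery(table[table.group != "stasis"], target="stasis")
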