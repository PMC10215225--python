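"""Evaluation protocol vs independent oracles.

AUC is checked against exhaustive pair counting, the operating point
against a brute-force threshold sweep, and the Welch p-value against
numerical integration of the t density.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammoscale.evaluation import (
    SingleClassError,
    auc,
    benign_vs_malignant_auc,
    normal_vs_abnormal_auc,
    operating_point,
    significance_stars,
    summarize_runs,
    welch_t_one_sided,
)
from mammoscale.training import RunResult


# -- oracles ---------------------------------------------------------------

def pair_counting_auc(scores, labels):
    """P(score_pos > score_neg) + ½ P(tie) by exhaustive enumeration."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def sweep_operating_point(scores, labels, target):
    """Brute force over all candidate thresholds."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    best = None
    for thr in np.unique(scores):
        se = (pos >= thr).mean()
        if se >= target and (best is None or thr > best):
            best = thr
    se = (pos >= best).mean()
    sp = (neg < best).mean()
    acc = ((pos >= best).sum() + (neg < best).sum()) / len(scores)
    return best, se, sp, acc


def quadrature_welch_p(t_stat, df):
    """Upper-tail t probability by trapezoidal integration of the density."""
    from scipy.special import gammaln

    x = np.linspace(-60, 60, 600_001)
    logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * np.log(df * np.pi)
    pdf = np.exp(logc - (df + 1) / 2 * np.log1p(x**2 / df))
    mask = x >= t_stat
    return float(np.trapezoid(pdf[mask], x[mask]))


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_worked_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            auc([0.1, 0.9], [1, 1])

    @given(
        st.lists(
            st.tuples(st.integers(0, 5), st.integers(0, 1)), min_size=2, max_size=12
        ).filter(lambda xs: len({l for _, l in xs}) == 2)
    )
    @settings(max_examples=200, deadline=None)
    def test_equals_pair_counting_oracle(self, pairs):
        """On every small score set (ties included, scores quantised to
        force them) AUC equals the exhaustive pair-counting statistic."""
        scores = [s / 5 for s, _ in pairs]
        labels = [l for _, l in pairs]
        assert auc(scores, labels) == pytest.approx(pair_counting_auc(scores, labels))


def _records(rows):
    return pd.DataFrame(rows, columns=["label", "lesion_type", "size_group"])


class TestGroupAucs:
    def _probs(self, n, rng):
        p = rng.random((n, 5))
        return p / p.sum(axis=1, keepdims=True)

    def test_balanced_subset_and_missing(self):
        rng = np.random.default_rng(0)
        rows = (
            [("malignant_mass", "mass", "small")] * 6
            + [("background", None, None)] * 20
        )
        probs = self._probs(len(rows), rng)
        a = normal_vs_abnormal_auc(probs, _records(rows), "mass", "small", seed=1)
        assert a is not None and 0 <= a <= 1
        assert normal_vs_abnormal_auc(probs, _records(rows), "calcification", "small") is None
        assert normal_vs_abnormal_auc(probs, _records(rows), "mass", "large") is None

    def test_subset_shared_across_models(self):
        """The background subsample depends on (group, seed) only."""
        rng = np.random.default_rng(1)
        rows = (
            [("benign_calc", "calcification", "medium")] * 5
            + [("background", None, None)] * 50
        )
        rec = _records(rows)
        probs = self._probs(len(rows), rng)
        ideal = np.zeros((len(rows), 5))
        ideal[:5, 1] = 1.0
        ideal[5:, 0] = 1.0
        # a perfect model must get AUC 1 on the same subset any model sees
        assert normal_vs_abnormal_auc(ideal, rec, "calcification", "medium", seed=3) == 1.0
        a1 = normal_vs_abnormal_auc(probs, rec, "calcification", "medium", seed=3)
        a2 = normal_vs_abnormal_auc(probs, rec, "calcification", "medium", seed=3)
        assert a1 == a2

    def test_benign_vs_malignant(self):
        rows = (
            [("malignant_mass", "mass", "large")] * 4
            + [("benign_mass", "mass", "large")] * 4
            + [("background", None, None)] * 5
        )
        rec = _records(rows)
        probs = np.zeros((len(rows), 5))
        probs[:4, 4] = 1.0  # malignant mass probability
        probs[4:8, 3] = 1.0
        probs[8:, 0] = 1.0
        assert benign_vs_malignant_auc(probs, rec, "mass", "large") == 1.0
        # single-pathology group is missing
        assert benign_vs_malignant_auc(probs, rec, "calcification", "small") is None
        only_benign = _records([("benign_mass", "mass", "small")] * 6)
        assert benign_vs_malignant_auc(np.ones((6, 5)) / 5, only_benign, "mass", "small") is None


class TestOperatingPoint:
    def test_distinct_scores_hit_target_exactly(self):
        rng = np.random.default_rng(0)
        pos = rng.permutation(np.linspace(0.3, 0.99, 100))
        neg = rng.uniform(0, 0.5, 100)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(100), np.zeros(100)])
        op = operating_point(scores, labels, target_se=0.75)
        assert op.se == pytest.approx(0.75)

    def test_separation_gives_full_specificity(self):
        scores = np.concatenate([np.linspace(0.6, 0.9, 20), np.linspace(0.1, 0.4, 20)])
        labels = np.concatenate([np.ones(20), np.zeros(20)])
        op = operating_point(scores, labels)
        assert op.se >= 0.75 and op.sp == 1.0

    @given(st.lists(st.tuples(st.integers(0, 8), st.integers(0, 1)), min_size=4, max_size=10)
           .filter(lambda xs: len({l for _, l in xs}) == 2))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_sweep(self, pairs):
        scores = [s / 8 for s, _ in pairs]
        labels = [l for _, l in pairs]
        op = operating_point(scores, labels, target_se=0.75)
        thr, se, sp, acc = sweep_operating_point(scores, labels, 0.75)
        assert op.threshold == pytest.approx(thr)
        assert (op.se, op.sp, op.acc) == pytest.approx((se, sp, acc))

    def test_accuracy_identity(self):
        rng = np.random.default_rng(3)
        scores = rng.random(30)
        labels = (rng.random(30) < 0.4).astype(int)
        labels[0] = 1
        op = operating_point(scores, labels)
        p, n = labels.sum(), (1 - labels).sum()
        assert op.acc == pytest.approx((op.se * p + op.sp * n) / (p + n))

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            operating_point([0.2, 0.4], [0, 0])


class TestWelch:
    def test_identical_samples_give_half(self):
        assert welch_t_one_sided(0.5, 0.0, 5, 0.5, 0.0, 5) == 0.5

    def test_reference_auc_rows_land_in_point_one_bin(self):
        """0.784 ± 0.002 vs 0.776 ± 0.010 at n = 5 per side: the printed
        significance bin is "<0.1" (and not "<0.05")."""
        p = welch_t_one_sided(0.784, 0.002, 5, 0.776, 0.010, 5)
        assert 0.05 < p < 0.1
        assert significance_stars(p) == "*"

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            ma, mb = rng.normal(0, 1, 2)
            sa, sb = rng.uniform(0.05, 1.0, 2)
            na, nb = rng.integers(3, 12, 2)
            va, vb = sa**2 / na, sb**2 / nb
            t = (ma - mb) / np.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
            p = welch_t_one_sided(ma, sa, na, mb, sb, nb)
            assert p == pytest.approx(quadrature_welch_p(t, df), abs=5e-5)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            welch_t_one_sided(0, 1, 1, 0, 1, 5)
        with pytest.raises(ValueError):
            welch_t_one_sided(0, -1, 5, 0, 1, 5)


class TestStars:
    @pytest.mark.parametrize(
        "p,label",
        [
            (0.0005, "****"),
            (0.005, "***"),
            (0.03, "**"),
            (0.07, "*"),
            (0.1, "ns"),  # boundary is strict
            (0.5, "ns"),
            (0.001, "***"),
            (0.05, "*"),
        ],
    )
    def test_bins(self, p, label):
        assert significance_stars(p) == label

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)


class TestSummarizeRuns:
    def _runs(self, scores_list, labels):
        return [
            RunResult(i, i, np.asarray(s), np.asarray(labels))
            for i, s in enumerate(scores_list)
        ]

    def test_identical_runs_have_zero_sd(self):
        labels = [1, 1, 0, 0]
        runs = self._runs([[0.9, 0.8, 0.2, 0.1]] * 5, labels)
        table = summarize_runs({"a": runs, "b": runs}, baseline="a")
        assert len(table) == 2
        assert table.set_index("model").loc["a", "auc_sd"] == 0.0

    def test_means_match_hand_average(self):
        labels = [1, 1, 1, 0, 0, 0]
        s1 = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]  # AUC 1
        s2 = [0.9, 0.8, 0.25, 0.3, 0.2, 0.1]  # 8 of 9 pairs ordered: AUC 8/9
        table = summarize_runs(
            {"m": self._runs([s1, s2], labels), "base": self._runs([s1, s1], labels)},
            baseline="base",
        )
        auc_mean = table.set_index("model").loc["m", "auc_mean"]
        assert auc_mean == pytest.approx((1.0 + 8 / 9) / 2)

    def test_mismatched_eval_sets_rejected(self):
        a = self._runs([[0.9, 0.1]] * 2, [1, 0])
        b = self._runs([[0.9, 0.1]] * 2, [0, 1])
        with pytest.raises(ValueError, match="mismatched"):
            summarize_runs({"a": a, "b": b}, baseline="a")

    def test_missing_baseline_rejected(self):
        a = self._runs([[0.9, 0.1]] * 2, [1, 0])
        with pytest.raises(ValueError, match="baseline"):
            summarize_runs({"a": a}, baseline="z")
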