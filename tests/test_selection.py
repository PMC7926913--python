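"""Selection tests: Tukey screen vs scipy, pruning, stepwise searches."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import tukey_hsd

from oliveauth import (
    anova_tukey_select,
    prune_correlated,
    stepwise_lda_select,
    stepwise_lr_select,
)
from oliveauth.selection import tukey_screen
from oliveauth import models

from conftest import table_from_matrix

GROUPS_22 = ["Esp"] * 6 + ["Gre"] * 5 + ["Ita"] * 6 + ["Pt"] * 5


class TestTukeyScreen:
    def test_matches_scipy_tukey_hsd_decisions_and_pvalues(self):
        """Dual route: the vectorised screen must agree with scipy's
        Tukey-Kramer implementation bucket by bucket (unbalanced groups)."""
        rng = np.random.default_rng(4)
        sizes = {"Esp": 8, "Gre": 5, "Ita": 11, "Pt": 6}
        groups = [g for g, n in sizes.items() for _ in range(n)]
        matrix = rng.normal(0, 1, (sum(sizes.values()), 40))
        matrix[:, :10] += np.where(np.array(groups)[:, None] == "Ita", 2.0, 0.0)[:, :10]
        X = pd.DataFrame(matrix, columns=[f"b{j}" for j in range(40)])
        stats = tukey_screen(X, pd.Series(groups), alpha=0.05)
        for j in range(40):
            samples = [matrix[np.array(groups) == g, j] for g in sorted(sizes)]
            res = tukey_hsd(*samples)
            pmin = min(
                res.pvalue[a, b]
                for a, b in itertools.combinations(range(4), 2)
            )
            assert stats["keep"].iloc[j] == (pmin < 0.05)
            if stats["keep"].iloc[j]:
                assert stats["min_tukey_p"].iloc[j] == pytest.approx(pmin, rel=1e-6, abs=1e-9)

    def test_constant_bucket_removed_and_exact_difference_kept(self):
        matrix = np.ones((22, 2))
        matrix[:6, 1] = 2.0  # Esp differs exactly, zero within-group variance
        t = table_from_matrix(matrix, GROUPS_22)
        res = anova_tukey_select(t)
        assert res.selected == [t.bucket_ids[1]]

    def test_two_plus_rule_is_stricter(self):
        rng = np.random.default_rng(9)
        matrix = rng.normal(0, 1, (22, 30))
        # one group mildly shifted: often significant vs one group only
        matrix[:6] += 1.2
        t = table_from_matrix(matrix, GROUPS_22)
        any_pair = anova_tukey_select(t, rule="any_pair").selected
        two_plus = anova_tukey_select(t, rule="two_plus").selected
        assert set(two_plus) <= set(any_pair)

    def test_power_for_large_shift(self):
        rng = np.random.default_rng(1)
        matrix = rng.normal(0, 1, (22, 20))
        matrix[6:11] += 10.0  # Gre shifted 10 pooled SDs
        t = table_from_matrix(matrix, GROUPS_22)
        assert len(anova_tukey_select(t).selected) == 20


class TestPruneCorrelated:
    def _table(self, cols, rts):
        matrix = np.column_stack(cols)
        return table_from_matrix(matrix, GROUPS_22, rts=np.array(rts))

    def test_duplicated_column_at_same_rt_collapses(self):
        rng = np.random.default_rng(2)
        x = rng.random(22)
        t = self._table([x, x], [5.0, 5.003])
        res = prune_correlated(t, list(t.bucket_ids))
        assert len(res.selected) == 1

    def test_threshold_is_strict_on_absolute_r(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=22)
        neg = -x + rng.normal(0, 0.28, 22)  # |r| ~ 0.96
        weak = 0.5 * x + rng.normal(0, 1.0, 22)  # |r| ~ 0.5
        t = self._table([x, neg, weak], [5.0, 5.002, 5.004])
        assert abs(np.corrcoef(x, neg)[0, 1]) > 0.8
        assert abs(np.corrcoef(x, weak)[0, 1]) < 0.8
        res = prune_correlated(t, list(t.bucket_ids))
        assert len(res.selected) == 2

    def test_correlated_but_different_rt_both_kept(self):
        rng = np.random.default_rng(4)
        x = rng.random(22)
        t = self._table([x, x], [5.0, 9.0])
        res = prune_correlated(t, list(t.bucket_ids))
        assert len(res.selected) == 2

    def test_idempotent_and_no_surviving_correlated_same_rt_pair(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(22, 4))
        cols = [base[:, j % 4] + rng.normal(0, 0.2, 22) for j in range(12)]
        rts = [5.0 + 0.002 * j for j in range(12)]  # all within 0.5 s of neighbours
        t = self._table(cols, rts)
        res = prune_correlated(t, list(t.bucket_ids))
        again = prune_correlated(t, res)
        assert again.selected == res.selected
        X = t.intensities
        rt = t.buckets["rt_min"]
        for a, b in itertools.combinations(res.selected, 2):
            if abs(rt[a] - rt[b]) <= 0.5 / 60:
                assert abs(np.corrcoef(X[a], X[b])[0, 1]) <= 0.8


class TestStepwiseLDA:
    def test_recovers_two_separating_variables_among_noise(self):
        rng = np.random.default_rng(6)
        n = 48
        groups = ["Esp"] * 14 + ["Gre"] * 10 + ["Ita"] * 14 + ["Pt"] * 10
        matrix = rng.normal(0, 1, (n, 52))
        g = np.array(groups)
        # two variables jointly separate the four groups
        matrix[:, 0] += np.select([g == "Esp", g == "Gre"], [8.0, 8.0], 0.0)
        matrix[:, 1] += np.select([g == "Esp", g == "Ita"], [8.0, 8.0], 0.0)
        t = table_from_matrix(matrix, groups)
        res = stepwise_lda_select(t, seed=1)
        assert set(t.bucket_ids[:2]) <= set(res.selected[:3])
        assert res.details["val_misclass"].min() == 0.0

    def test_permuted_labels_give_small_selection_and_low_entropy_r2(self):
        rng = np.random.default_rng(7)
        matrix = rng.normal(0, 1, (44, 30))
        groups = list(rng.permutation(["Esp"] * 12 + ["Gre"] * 10 + ["Ita"] * 12 + ["Pt"] * 10))
        t = table_from_matrix(matrix, groups)
        res = stepwise_lda_select(t, seed=2)
        if res.trace:
            assert res.trace[-1] < 0.5
        assert len(res.selected) <= 5

    def test_single_candidate_selects_at_most_one(self):
        rng = np.random.default_rng(8)
        t = table_from_matrix(rng.normal(0, 1, (22, 1)), GROUPS_22)
        res = stepwise_lda_select(t, seed=0)
        assert len(res.selected) <= 1

    def test_trace_training_error_is_non_increasing(self):
        rng = np.random.default_rng(9)
        matrix = rng.normal(0, 1, (44, 20))
        g = np.array(["Esp"] * 12 + ["Gre"] * 10 + ["Ita"] * 12 + ["Pt"] * 10)
        matrix[:, 0] += (g == "Ita") * 3.0
        matrix[:, 1] += (g == "Esp") * 3.0
        t = table_from_matrix(matrix, list(g))
        res = stepwise_lda_select(t, seed=3)
        errs = list(res.details["train_misclass"])
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


class TestStepwiseLR:
    def test_matches_exhaustive_best_subset_oracle(self):
        """On a designed instance with one dominant predictor, BIC-forward
        selection must find the same set as exhaustive best-subset search."""
        rng = np.random.default_rng(10)
        n = 120
        X = rng.normal(0, 1, (n, 8))
        eta = -0.5 + 2.5 * X[:, 3]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        groups = ["Ita"] * 60 + ["Esp"] * 60
        t = table_from_matrix(X, groups)
        res = stepwise_lr_select(t, y, target="Ita")

        best_bic, best_subset = np.inf, ()
        for r in range(0, 9):
            for subset in itertools.combinations(range(8), r):
                cols = [t.bucket_ids[j] for j in subset]
                fit = models.lr_fit(t.intensities[cols], y)
                if fit.bic < best_bic:
                    best_bic, best_subset = fit.bic, cols
        assert set(res.selected) == set(best_subset)

    def test_null_data_selects_nothing(self):
        rng = np.random.default_rng(11)
        X = rng.normal(0, 1, (150, 10))
        y = (rng.random(150) < 0.5).astype(float)
        t = table_from_matrix(X, ["Ita"] * 75 + ["Esp"] * 75)
        res = stepwise_lr_select(t, y)
        assert len(res.selected) <= 1

    def test_zero_candidates_select_nothing(self):
        t = table_from_matrix(np.zeros((10, 0)), ["Ita"] * 5 + ["Esp"] * 5)
        res = stepwise_lr_select(t, np.array([1.0] * 5 + [0.0] * 5))
        assert res.selected == []

    def test_bic_trace_strictly_decreases(self):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 1, (100, 6))
        eta = 1.5 * X[:, 0] - 1.5 * X[:, 1]
        y = (rng.random(100) < 1 / (1 + np.exp(-eta))).astype(float)
        t = table_from_matrix(X, ["Ita"] * 50 + ["Esp"] * 50)
        res = stepwise_lr_select(t, y)
        null_bic = models.lr_fit(t.intensities[[]], y).bic
        trace = [null_bic] + res.trace
        assert all(a > b for a, b in zip(trace, trace[1:]))


def test_strategies_recover_planted_markers(small_dataset, small_filtered):
    """With one >= 4-fold marker per origin, the univariate screen and the
    union of per-country stepwise-LR selections recover >= 80% of the
    planted marker buckets.

    Stepwise LDA sized by validation entropy R^2 legitimately stops before
    exhausting the markers (any 3 of 4 already separate the four classes),
    so for it the recoverability property is that markers lead the forward
    search path and the sized selection contains only markers.
    """
    from oliveauth.pipeline import match_marker_buckets

    mapping = match_marker_buckets(small_filtered, small_dataset.ground_truth)
    marker_buckets = {b for b in mapping.values() if b is not None}
    n_markers = len(mapping)

    anova = prune_correlated(small_filtered, anova_tukey_select(small_filtered))
    assert len(marker_buckets & set(anova.selected)) >= 0.8 * n_markers

    lda = stepwise_lda_select(small_filtered, seed=0)
    explored = list(lda.details["variable"])
    assert set(explored[:3]) <= marker_buckets
    assert set(lda.selected) <= marker_buckets

    union = set()
    for country in small_filtered.origin_groups:
        y = (small_filtered.groups == country).astype(float)
        union |= set(stepwise_lr_select(small_filtered, y, target=country).selected)
    assert len(marker_buckets & union) >= 0.8 * n_markers
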