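"""Filter-cascade tests: hand oracles, boundary semantics, invariants."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oliveauth import (
    ConfigError,
    FilterConfig,
    average_duplicates,
    filter_blank_ratio,
    filter_fold_change,
    filter_presence,
    generate_dataset,
    run_filter_cascade,
    build_bucket_table,
    SimConfig,
)

from conftest import table_from_matrix


def means_table(group_means: dict[str, list[float]], n_per_group: int = 2):
    """Injection-level table whose group means equal the given values exactly."""
    rows, groups, oils, reps = [], [], [], []
    for g, vals in group_means.items():
        for i in range(n_per_group):
            rows.append(vals)
            groups.append(g)
            oils.append(f"{g}{i}")
            reps.append(1)
    return table_from_matrix(np.array(rows, float), groups, oil_ids=oils, replicates=reps)


class TestBlankRatio:
    def test_kept_when_one_group_clears_twice_the_blank(self):
        # group means Ita 10, others 0; blank mean 5 -> 10 >= 2*5 kept
        t = means_table({"Ita": [10.0], "Esp": [0.0], "Gre": [0.0], "Pt": [0.0], "Blank": [5.0]})
        assert filter_blank_ratio(t).n_buckets == 1
        # blank mean 5.1 -> 10 < 10.2 removed
        t2 = means_table({"Ita": [10.0], "Esp": [0.0], "Blank": [5.1]})
        assert filter_blank_ratio(t2).n_buckets == 0

    def test_all_zero_bucket_removed(self):
        t = means_table({"Ita": [0.0], "Esp": [0.0], "Blank": [0.0]})
        assert filter_blank_ratio(t).n_buckets == 0

    def test_zero_blank_mean_keeps_any_expressed_bucket(self):
        t = means_table({"Ita": [0.1], "Esp": [0.0], "Blank": [0.0]})
        assert filter_blank_ratio(t).n_buckets == 1

    def test_missing_blank_group_is_an_error(self):
        t = means_table({"Ita": [1.0], "Esp": [1.0]})
        with pytest.raises(ConfigError, match="skip"):
            filter_blank_ratio(t)


class TestPresence:
    def test_strictly_more_than_half_of_one_group(self):
        # 13 samples, 7 nonzero -> 7/13 > 0.5 kept; 6 nonzero everywhere removed
        col_kept = [1.0] * 7 + [0.0] * 6
        col_removed = [1.0] * 6 + [0.0] * 7
        matrix = np.array([col_kept, col_removed]).T
        t = table_from_matrix(matrix, ["Gre"] * 13)
        out = filter_presence(t)
        assert out.bucket_ids == [t.bucket_ids[0]]

    def test_exactly_half_is_removed(self):
        matrix = np.array([[1.0]] * 6 + [[0.0]] * 6)
        t = table_from_matrix(matrix, ["Ita"] * 12)
        assert filter_presence(t).n_buckets == 0

    def test_blanks_do_not_count_toward_presence(self):
        matrix = np.array([[0.0], [0.0], [1.0], [1.0]])
        t = table_from_matrix(matrix, ["Ita", "Ita", "Blank", "Blank"])
        assert filter_presence(t).n_buckets == 0

    def test_matches_brute_force_counting_oracle(self):
        rng = np.random.default_rng(0)
        matrix = rng.random((40, 30)) * (rng.random((40, 30)) < 0.5)
        groups = ["Esp"] * 12 + ["Gre"] * 8 + ["Ita"] * 14 + ["Pt"] * 6
        t = table_from_matrix(matrix, groups)
        out = set(filter_presence(t, 0.5).bucket_ids)
        expected = set()
        for j, b in enumerate(t.bucket_ids):
            for g in ("Esp", "Gre", "Ita", "Pt"):
                rows = [i for i, gg in enumerate(groups) if gg == g]
                if sum(matrix[i, j] > 0 for i in rows) / len(rows) > 0.5:
                    expected.add(b)
                    break
        assert out == expected


class TestAverageDuplicates:
    def test_duplicate_pair_averages(self):
        t = table_from_matrix(
            [[4.0], [6.0]], ["Ita", "Ita"], oil_ids=["oil1", "oil1"], replicates=[1, 2]
        )
        out = average_duplicates(t)
        assert out.n_samples == 1
        assert out.intensities.iloc[0, 0] == pytest.approx(5.0)
        assert out.samples["n_injections"].iloc[0] == 2

    def test_row_count_collapses_to_one_per_oil(self, small_table, small_config):
        out = average_duplicates(small_table)
        n_oils = sum(small_config.n_per_group.values())
        assert out.n_samples == n_oils + small_config.n_blanks

    def test_missing_injection_uses_available_value_with_warning(self, caplog):
        t = table_from_matrix(
            [[4.0], [6.0], [8.0]],
            ["Ita", "Ita", "Ita"],
            oil_ids=["oil1", "oil1", "oil2"],
            replicates=[1, 2, 1],
        )
        with caplog.at_level("WARNING", logger="oliveauth"):
            out = average_duplicates(t)
        assert "oil2" in caplog.text
        assert out.intensities.loc["oil2"].iloc[0] == pytest.approx(8.0)


class TestFoldChange:
    def test_boundary_inclusive(self):
        kept = means_table({"Esp": [2.0], "Gre": [3.0], "Ita": [4.0], "Pt": [5.0]})
        assert filter_fold_change(kept).n_buckets == 1  # 5/2 = 2.5 >= 2
        removed = means_table({"Esp": [3.0], "Gre": [4.0], "Ita": [5.0], "Pt": [5.9]})
        assert filter_fold_change(removed).n_buckets == 0  # 5.9/3 < 2
        exact = means_table({"Esp": [2.0], "Gre": [4.0]})
        assert filter_fold_change(exact).n_buckets == 1  # 4/2 = 2 inclusive

    def test_zero_minimum_keeps_expressed_bucket(self):
        t = means_table({"Esp": [0.0], "Ita": [1.0]})
        assert filter_fold_change(t).n_buckets == 1
        z = means_table({"Esp": [0.0], "Ita": [0.0]})
        assert filter_fold_change(z).n_buckets == 0

    def test_single_group_is_an_error(self):
        t = means_table({"Ita": [1.0]})
        with pytest.raises(ConfigError, match="two origin groups"):
            filter_fold_change(t)

    def test_matches_min_max_ratio_oracle(self):
        rng = np.random.default_rng(3)
        matrix = rng.lognormal(0, 1, (20, 40))
        groups = ["Esp"] * 6 + ["Gre"] * 4 + ["Ita"] * 6 + ["Pt"] * 4
        t = table_from_matrix(matrix, groups)
        out = set(filter_fold_change(t).bucket_ids)
        gm = pd.DataFrame(matrix).groupby(pd.Series(groups)).mean()
        expected = {
            b
            for j, b in enumerate(t.bucket_ids)
            if gm[j].max() >= 2 * gm[j].min() and gm[j].max() > 0
        }
        assert out == expected


class TestCascade:
    def test_ten_bucket_hand_oracle(self):
        """Survivor set of the full cascade matches the hand computation.

        Bucket layout (columns), group means set by construction:
          0 contaminant-like: equal in oils and blank      -> fails (i)
          1 clean marker Ita 10 vs 1 elsewhere, blank 0    -> survives all
          2 rare: present in 1 of 4 samples per group      -> fails (ii)
          3 flat across groups, blank 0                    -> fails (iii)
          4 2-fold Esp vs Pt, blank low                    -> survives all
          5 all zero                                       -> fails (i)
          6 blank-dominated (blank 10, oils 4)             -> fails (i)
          7 exactly 2x blank                               -> passes (i); flat -> fails (iii)
          8 marker Gre, but only in 50% of Gre samples     -> fails (ii)
          9 marker Pt 5-fold, blank 0                      -> survives all
        """
        groups4 = ["Esp", "Gre", "Ita", "Pt"]
        rows, labels, oils, reps = [], [], [], []
        for g in groups4:
            for oil in range(2):
                for rep in (1, 2):
                    present_rare = 1.0 if (oil == 0 and rep == 1) else 0.0
                    half_gre = 1.0 if (g == "Gre" and oil == 0) else 0.0
                    rows.append(
                        [
                            5.0,
                            10.0 if g == "Ita" else 1.0,
                            present_rare,
                            3.0,
                            4.0 if g == "Esp" else 2.0,
                            0.0,
                            4.0,
                            6.0,
                            20.0 * half_gre,
                            5.0 if g == "Pt" else 1.0,
                        ]
                    )
                    labels.append(g)
                    oils.append(f"{g}{oil}")
                    reps.append(rep)
        for b in range(2):  # two blank events
            rows.append([5.0, 0.0, 0.0, 0.0, 1.0, 0.0, 10.0, 3.0, 0.0, 0.0])
            labels.append("Blank")
            oils.append(f"Blank{b}")
            reps.append(1)
        t = table_from_matrix(np.array(rows), labels, oil_ids=oils, replicates=reps)
        out, report = run_filter_cascade(t)
        survivors = {int(b.split("_")[0][1:]) for b in out.bucket_ids}
        assert survivors == {1, 4, 9}
        counts = [s["buckets_out"] for s in report.stages]
        assert counts == [7, 5, 5, 3]

    def test_empty_table_passes_through_with_zero_counts(self):
        t = table_from_matrix(
            np.zeros((4, 0)), ["Esp", "Gre", "Ita", "Blank"],
        )
        out, report = run_filter_cascade(t)
        assert out.n_buckets == 0
        assert all(s["buckets_in"] == 0 and s["buckets_out"] == 0 for s in report.stages)

    def test_stage_counts_weakly_decrease(self, small_table):
        _, report = run_filter_cascade(small_table)
        counts = [small_table.n_buckets] + [s["buckets_out"] for s in report.stages]
        # duplicate averaging does not change the bucket count
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_planted_markers_survive_and_survivors_verified_by_oracle(
        self, small_dataset, small_table, small_filtered
    ):
        from oliveauth.pipeline import match_marker_buckets

        mapping = match_marker_buckets(small_filtered, small_dataset.ground_truth)
        marker_buckets = {b for b in mapping.values() if b is not None}
        assert len(marker_buckets) == len(small_dataset.ground_truth.markers)
        assert marker_buckets <= set(small_filtered.bucket_ids)
        # every survivor passes the min/max ratio rule on the averaged table
        averaged = average_duplicates(small_table)
        gm = averaged.group_means()
        for b in small_filtered.bucket_ids:
            col = gm[b]
            assert col.max() >= 2 * col.min() or col.min() == 0

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, deadline=None)
    def test_monotone_reduction_and_scale_invariance(self, seed):
        """Each stage keeps a subset of buckets; criteria (i)/(iii) and the
        whole cascade ignore a global positive rescaling of intensities."""
        rng = np.random.default_rng(seed)
        n_b = int(rng.integers(1, 12))
        groups = ["Esp"] * 4 + ["Gre"] * 3 + ["Ita"] * 4 + ["Pt"] * 3 + ["Blank"] * 2
        oils = [f"{g}{i // 2}" for i, g in enumerate(groups[:-2])] + ["bl1", "bl2"]
        matrix = rng.lognormal(0, 1, (16, n_b)) * (rng.random((16, n_b)) < 0.7)
        t = table_from_matrix(matrix, groups, oil_ids=oils)
        out, report = run_filter_cascade(t)
        assert set(out.bucket_ids) <= set(t.bucket_ids)
        counts = [s["buckets_out"] for s in report.stages]
        assert all(a >= b for a, b in zip([n_b] + counts, counts))
        scaled, _ = run_filter_cascade(t.with_intensities(t.intensities * 37.5))
        assert scaled.bucket_ids == out.bucket_ids

    def test_qualitative_reduction_shape_on_paper_like_structure(self):
        """Blank criterion removes few buckets, presence the large majority,
        fold change a further modest fraction."""
        config = SimConfig(
            n_per_group={"Esp": 8, "Gre": 4, "Ita": 12, "Pt": 5},
            n_blanks=6,
            n_background=400,
            n_contaminants=12,
            presence_prob=(0.25, 0.8),  # many rarely-detected features
            seed=19,
        )
        ds = generate_dataset(config)
        table = build_bucket_table(ds.feature_lists)
        _, report = run_filter_cascade(table)
        n0 = report.stages[0]["buckets_in"]
        after_blank = report.stages[0]["buckets_out"]
        after_presence = report.stages[1]["buckets_out"]
        after_fold = report.stages[3]["buckets_out"]
        assert (n0 - after_blank) / n0 < 0.15          # (i) removes few
        assert (after_blank - after_presence) / after_blank > 0.5  # (ii) removes most
        assert after_fold < after_presence              # (iii) trims further


def test_filter_config_validation():
    with pytest.raises(ConfigError, match="presence_frac"):
        FilterConfig(presence_frac=1.5).validate()
    with pytest.raises(ConfigError, match="blank_factor"):
        FilterConfig(blank_factor=0.5).validate()
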