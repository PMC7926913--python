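"""Shared fixtures: small synthetic cohorts and hand-built bucket tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from oliveauth import BucketTable, SimConfig, generate_dataset
from oliveauth._core import FeatureList, SampleMeta


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down cohort: 24 oils, duplicates, blanks, one 4-fold marker/group."""
    return SimConfig(
        n_per_group={"Esp": 7, "Gre": 5, "Ita": 7, "Pt": 5},
        n_blanks=4,
        n_background=120,
        n_contaminants=12,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    from oliveauth import build_bucket_table

    return build_bucket_table(small_dataset.feature_lists)


@pytest.fixture(scope="session")
def small_filtered(small_table):
    from oliveauth import run_filter_cascade

    filtered, _ = run_filter_cascade(small_table)
    return filtered


def make_feature_list(sample_id, group, rows, oil_id=None, replicate=1):
    """Build a FeatureList from (rt_min, mz, intensity) tuples."""
    df = pd.DataFrame(rows, columns=["rt_min", "mz", "intensity"])
    return FeatureList(
        SampleMeta(sample_id, oil_id or sample_id, group, replicate), df
    )


def table_from_matrix(matrix, groups, oil_ids=None, replicates=None, rts=None, mzs=None):
    """Build a BucketTable directly from a 2-D array and group labels.

    Gaussian test matrices are shifted to be non-negative (intensities
    cannot be negative); a global location shift leaves every statistic
    exercised in the tests unchanged.
    """
    matrix = np.asarray(matrix, float)
    if matrix.size and matrix.min() < 0:
        matrix = matrix - matrix.min()
    n, p = matrix.shape
    sample_ids = [f"s{i:02d}" for i in range(n)]
    oil_ids = oil_ids or sample_ids
    replicates = replicates if replicates is not None else [1] * n
    rts = rts if rts is not None else np.linspace(1.0, 16.0, p)
    mzs = mzs if mzs is not None else np.linspace(100.0, 900.0, p)
    bucket_ids = [f"B{j}_rt{rts[j]:.4f}_mz{mzs[j]:.4f}" for j in range(p)]
    buckets = pd.DataFrame(
        {"rt_min": rts, "mz": mzs}, index=pd.Index(bucket_ids, name="bucket_id")
    )
    samples = pd.DataFrame(
        {"oil_id": oil_ids, "group": list(groups), "replicate": replicates},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    intens = pd.DataFrame(matrix, index=samples.index, columns=buckets.index)
    return BucketTable(intens, buckets, samples)
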