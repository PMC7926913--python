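"""Shared containers and errors for the olive-oil origin workflow.

The whole pipeline revolves around two objects: per-sample feature lists
(one detected compound per row, characterised by retention time and m/z)
and the samples x buckets intensity matrix obtained by aligning those
lists across samples.  Both are thin dataclass wrappers around pandas
DataFrames so that every stage can use ordinary DataFrame operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("oliveauth")

#: Origin groups of the 95-oil reference design (Spain, Greece, Italy, Portugal).
ORIGIN_GROUPS = ("Esp", "Gre", "Ita", "Pt")
#: Group label for solvent-blank injections.
BLANK_GROUP = "Blank"

FEATURE_COLUMNS = ("rt_min", "mz", "intensity")
SAMPLE_COLUMNS = ("sample_id", "oil_id", "group", "replicate")


class ConfigError(ValueError):
    """An invalid configuration value; the message names the field."""


class ParseError(ValueError):
    """A malformed input file; the message names file, line and column."""


class SingularCovarianceError(ValueError):
    """Pooled covariance is singular (too many variables for the sample size)."""


class FeasibilityError(ValueError):
    """Cross-validation bounds are arithmetically incompatible with the counts."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one injection: which oil, which origin group, which replicate."""

    sample_id: str
    oil_id: str
    group: str
    replicate: int = 1


@dataclass
class FeatureList:
    """One sample's detected compounds as (rt_min, mz, intensity) records.

    Absence of a compound is represented by omission (no zero-intensity
    rows); intensities must be strictly positive.
    """

    sample: SampleMeta
    features: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_COLUMNS if c not in self.features.columns]
        if missing:
            raise ParseError(
                f"feature list for {self.sample.sample_id!r} lacks column(s) {missing}"
            )
        self.features = self.features.loc[:, list(FEATURE_COLUMNS)].reset_index(drop=True)
        if len(self.features) and (self.features["intensity"] <= 0).any():
            raise ConfigError(
                f"feature list for {self.sample.sample_id!r} contains non-positive intensities"
            )

    def __len__(self) -> int:
        return len(self.features)


def samples_frame(metas: Iterable[SampleMeta]) -> pd.DataFrame:
    """Metadata table (indexed by sample_id) from a sequence of SampleMeta."""
    rows = [(m.sample_id, m.oil_id, m.group, m.replicate) for m in metas]
    df = pd.DataFrame(rows, columns=list(SAMPLE_COLUMNS))
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ConfigError(f"duplicate sample_id {dup!r} in metadata")
    return df.set_index("sample_id")


@dataclass
class BucketTable:
    """Samples x buckets intensity matrix with bucket and sample metadata.

    Attributes
    ----------
    intensities
        DataFrame indexed by sample_id, one column per bucket, entries >= 0
        (0 means the compound was not detected in that sample).
    buckets
        DataFrame indexed by bucket_id with columns ``rt_min`` and ``mz``
        (intensity-weighted centroids of the contributing features).
    samples
        DataFrame indexed by sample_id with at least ``oil_id`` and
        ``group`` columns (``replicate`` before duplicate averaging,
        ``n_injections`` after).
    qc
        Free-form quality-control counters accumulated by the producer
        (excluded features, same-sample merges, ...).
    """

    intensities: pd.DataFrame
    buckets: pd.DataFrame
    samples: pd.DataFrame

    qc: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.intensities.index.equals(self.samples.index):
            raise ConfigError("intensity matrix rows do not match the sample metadata")
        if not self.intensities.columns.equals(self.buckets.index):
            raise ConfigError("intensity matrix columns do not match the bucket metadata")
        if len(self.intensities) and (self.intensities.to_numpy() < 0).any():
            raise ConfigError("bucket table contains negative intensities")

    # ------------------------------------------------------------------ views
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_buckets(self) -> int:
        return self.intensities.shape[1]

    @property
    def bucket_ids(self) -> list[str]:
        return list(self.buckets.index)

    @property
    def groups(self) -> pd.Series:
        return self.samples["group"]

    @property
    def origin_groups(self) -> list[str]:
        return [g for g in pd.unique(self.groups) if g != BLANK_GROUP]

    def has_blanks(self) -> bool:
        return bool((self.groups == BLANK_GROUP).any())

    # ------------------------------------------------------------- operations
    def group_means(self, include_blank: bool = False) -> pd.DataFrame:
        """Mean intensity per group (rows) per bucket (columns)."""
        mask = np.ones(self.n_samples, dtype=bool)
        if not include_blank:
            mask = (self.groups != BLANK_GROUP).to_numpy()
        sub = self.intensities.loc[mask]
        return sub.groupby(self.groups.loc[mask], observed=True).mean()

    def subset(self, bucket_ids: Sequence[str]) -> "BucketTable":
        """Restrict to the given buckets (order preserved as given)."""
        ids = list(bucket_ids)
        return BucketTable(
            intensities=self.intensities.loc[:, ids].copy(),
            buckets=self.buckets.loc[ids].copy(),
            samples=self.samples.copy(),
            qc=dict(self.qc),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "BucketTable":
        """Restrict to the given samples (order preserved as given)."""
        ids = list(sample_ids)
        return BucketTable(
            intensities=self.intensities.loc[ids].copy(),
            buckets=self.buckets.copy(),
            samples=self.samples.loc[ids].copy(),
            qc=dict(self.qc),
        )

    def drop_blanks(self) -> "BucketTable":
        keep = self.samples.index[self.groups != BLANK_GROUP]
        return self.subset_samples(list(keep))

    def copy(self) -> "BucketTable":
        return BucketTable(
            intensities=self.intensities.copy(),
            buckets=self.buckets.copy(),
            samples=self.samples.copy(),
            qc=dict(self.qc),
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "BucketTable":
        return replace(self, intensities=intensities)
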