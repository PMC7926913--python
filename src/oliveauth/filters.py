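"""Three-criterion bucket-reduction cascade with duplicate averaging.

A bucket survives the cascade when, in this fixed order,

(i)   the mean of at least one origin group is at least ``blank_factor``
      times the blank-group mean (computed on injection-level rows),
(ii)  more than ``presence_frac`` of the samples of at least one origin
      group have a value > 0 (strict inequality),
(then the duplicate injections of each oil are averaged), and
(iii) the highest origin-group mean is at least ``fold_change`` times the
      lowest one.

Boundary semantics: "two-fold higher" / "at least two-fold change" are
inclusive (>=), "more than 50%" is strict (>).  A zero denominator (blank
mean or lowest group mean of 0) passes whenever the numerator is positive,
the ratio being unbounded; all three thresholds are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._core import BLANK_GROUP, BucketTable, ConfigError, log

__all__ = [
    "FilterConfig",
    "FilterReport",
    "filter_blank_ratio",
    "filter_presence",
    "average_duplicates",
    "filter_fold_change",
    "run_filter_cascade",
]


@dataclass
class FilterConfig:
    """Thresholds of the reduction cascade (defaults per the reference method)."""

    blank_factor: float = 2.0
    presence_frac: float = 0.5
    fold_change: float = 2.0
    group_column: str = "group"

    def validate(self) -> None:
        if self.blank_factor < 1:
            raise ConfigError(f"blank_factor must be >= 1, got {self.blank_factor!r}")
        if not 0 < self.presence_frac < 1:
            raise ConfigError(f"presence_frac must lie in (0, 1), got {self.presence_frac!r}")
        if self.fold_change < 1:
            raise ConfigError(f"fold_change must be >= 1, got {self.fold_change!r}")


@dataclass
class FilterReport:
    """Per-stage bucket counts and per-bucket pass/fail flags."""

    stages: list[dict] = field(default_factory=list)
    #: stage name -> boolean Series indexed by that stage's input buckets
    flags: dict[str, pd.Series] = field(default_factory=dict)

    def add(self, stage: str, buckets_in: int, buckets_out: int, flags: pd.Series | None = None) -> None:
        self.stages.append({"stage": stage, "buckets_in": buckets_in, "buckets_out": buckets_out})
        if flags is not None:
            self.flags[stage] = flags

    def counts(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)

    def to_dict(self) -> dict:
        return {
            "stages": self.stages,
            "flags": {k: {b: bool(v) for b, v in s.items()} for k, s in self.flags.items()},
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        return path


def _origin_group_means(table: BucketTable) -> pd.DataFrame:
    gm = table.group_means(include_blank=False)
    if gm.empty and table.n_buckets:
        raise ConfigError("bucket table has no origin-group samples")
    return gm


def _keep(table: BucketTable, keep: pd.Series) -> BucketTable:
    return table.subset(list(table.intensities.columns[keep.to_numpy(bool)]))


def blank_ratio_flags(table: BucketTable, factor: float = 2.0) -> pd.Series:
    """Criterion (i) pass flags without subsetting the table."""
    if not table.has_blanks():
        raise ConfigError(
            "no Blank samples in the table; to run the cascade without a blank "
            "criterion, call run_filter_cascade(..., skip_blank_stage=True)"
        )
    gmax = _origin_group_means(table).max(axis=0)
    bmean = table.intensities.loc[table.groups == BLANK_GROUP].mean(axis=0)
    n_zero_blank = int(((bmean == 0) & (gmax > 0)).sum())
    if n_zero_blank:
        log.info("criterion (i): %d bucket(s) kept on zero blank mean", n_zero_blank)
    return (gmax > 0) & ((bmean == 0) | (gmax >= factor * bmean))


def filter_blank_ratio(table: BucketTable, factor: float = 2.0) -> BucketTable:
    """Criterion (i): some origin-group mean >= ``factor`` x blank mean."""
    return _keep(table, blank_ratio_flags(table, factor))


def presence_flags(table: BucketTable, frac: float = 0.5) -> pd.Series:
    groups = table.groups
    origin = groups != BLANK_GROUP
    if not origin.any():
        raise ConfigError("presence filter requires at least one origin group")
    sizes = groups[origin].value_counts()
    if (sizes == 0).any():
        raise ConfigError(f"empty origin group(s): {list(sizes[sizes == 0].index)}")
    nonzero = (table.intensities.loc[origin.to_numpy()] > 0).groupby(
        groups[origin], observed=True
    ).sum()
    fracs = nonzero.div(sizes, axis=0)
    return (fracs > frac).any(axis=0)


def filter_presence(table: BucketTable, frac: float = 0.5) -> BucketTable:
    """Criterion (ii): value > 0 for more than ``frac`` of some origin group."""
    return _keep(table, presence_flags(table, frac))


def average_duplicates(table: BucketTable) -> BucketTable:
    """Average duplicate injections: one row per oil (blanks per blank event).

    An oil with fewer injections than the modal count contributes the mean
    of the available values, with a logged warning.
    """
    if "oil_id" not in table.samples.columns:
        raise ConfigError("sample metadata lacks an 'oil_id' column")
    oil = table.samples["oil_id"]
    # blanks are single injections by design; only oils can "miss" a duplicate
    origin_oils = oil[table.groups != BLANK_GROUP]
    counts = origin_oils.value_counts()
    if len(counts) and counts.nunique() > 1:
        freq = counts.value_counts()
        modal = int(max(freq.index[freq == freq.max()]))  # ties -> larger count
        short = sorted(counts.index[counts < modal])
        if short:
            log.warning(
                "oil(s) with fewer than %d injections, using the available mean: %s",
                modal,
                ", ".join(map(str, short)),
            )
    order = list(dict.fromkeys(oil))
    means = table.intensities.groupby(oil, sort=False).mean().loc[order]
    samples = (
        table.samples.groupby(oil, sort=False)
        .agg(group=("group", "first"), n_injections=("group", "size"))
        .loc[order]
    )
    samples.insert(0, "oil_id", samples.index)
    samples.index.name = "sample_id"
    means.index.name = "sample_id"
    return BucketTable(means, table.buckets.copy(), samples, qc=dict(table.qc))


def fold_change_flags(table: BucketTable, factor: float = 2.0) -> pd.Series:
    gm = _origin_group_means(table)
    if len(gm) < 2:
        raise ConfigError("fold-change filter requires at least two origin groups")
    gmax, gmin = gm.max(axis=0), gm.min(axis=0)
    n_zero = int(((gmin == 0) & (gmax > 0)).sum())
    if n_zero:
        log.info("criterion (iii): %d bucket(s) kept on zero minimum group mean", n_zero)
    return (gmax > 0) & ((gmin == 0) | (gmax >= factor * gmin))


def filter_fold_change(table: BucketTable, factor: float = 2.0) -> BucketTable:
    """Criterion (iii): highest group mean >= ``factor`` x lowest group mean."""
    return _keep(table, fold_change_flags(table, factor))


def run_filter_cascade(
    table: BucketTable,
    config: FilterConfig | None = None,
    skip_blank_stage: bool = False,
) -> tuple[BucketTable, FilterReport]:
    """Apply (i), (ii), duplicate averaging, (iii) in order.

    Returns the duplicate-averaged surviving table (blank rows dropped at
    the end, their job done) and a :class:`FilterReport` of per-stage
    counts and flags.
    """
    config = config or FilterConfig()
    config.validate()
    report = FilterReport()

    if skip_blank_stage:
        log.info("blank-ratio stage explicitly skipped")
        report.add("blank_ratio", table.n_buckets, table.n_buckets)
    else:
        flags = blank_ratio_flags(table, config.blank_factor)
        out = _keep(table, flags)
        report.add("blank_ratio", table.n_buckets, out.n_buckets, flags)
        table = out

    flags = presence_flags(table, config.presence_frac)
    out = _keep(table, flags)
    report.add("presence", table.n_buckets, out.n_buckets, flags)
    table = out

    table = average_duplicates(table)
    report.add("average_duplicates", table.n_buckets, table.n_buckets)

    flags = fold_change_flags(table, config.fold_change)
    out = _keep(table, flags)
    report.add("fold_change", table.n_buckets, out.n_buckets, flags)

    result = out.drop_blanks()
    log.info(
        "filter cascade: %s",
        " -> ".join(str(s["buckets_out"]) for s in report.stages),
    )
    return result, report
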