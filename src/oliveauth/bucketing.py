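"""Align per-sample feature lists into one samples x buckets table.

Features detected independently in different injections are combined into
"buckets" using a retention-time window of 0.5 s and a mass window of
5 mDa.  Two readings of "bucket width" are provided:

``cluster`` (default)
    Span-constrained clustering: features are visited in order of
    decreasing intensity; a feature may join an existing bucket if doing
    so keeps the bucket's total extent within one window in both
    dimensions (so contributing features always span <= 0.5 s and
    <= 5 mDa), choosing the nearest intensity-weighted centroid in
    window-normalised distance; otherwise it seeds a new bucket.  This
    avoids splitting a compound that happens to straddle a grid edge.

``grid``
    Fixed rectangular bins of exactly one window in each dimension,
    anchored at the low end of the valid RT/mass range — the literal
    "bucket width" reading.

If one sample contributes several features to a bucket their intensities
are summed (split detections of one compound); this is counted in the
table's QC dict.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._core import (
    BucketTable,
    ConfigError,
    FeatureList,
    ParseError,
    SAMPLE_COLUMNS,
    SampleMeta,
    log,
    samples_frame,
)

__all__ = [
    "build_bucket_table",
    "read_feature_lists",
    "write_bucket_table",
    "read_bucket_table",
]


def _cluster_assign(
    rt: np.ndarray,
    mz: np.ndarray,
    intensity: np.ndarray,
    rt_win: float,
    mz_win: float,
) -> np.ndarray:
    """Greedy span-constrained clustering; returns a bucket index per feature.

    A feature is eligible for a bucket when joining keeps the bucket's
    members within one window in both dimensions; the nearest eligible
    centroid (window-normalised distance, exact ties to the earliest
    bucket) wins.  An eligible bucket's centroid is always within one
    window of the feature, so with cell size equal to the window the 3x3
    cell neighbourhood of the feature contains every candidate.
    """
    # intensity-descending visit order; rt/mz break exact intensity ties
    order = np.lexsort((mz, rt, -intensity))
    assign = np.empty(rt.size, dtype=np.int64)
    cent_rt: list[float] = []
    cent_mz: list[float] = []
    lo_rt: list[float] = []
    hi_rt: list[float] = []
    lo_mz: list[float] = []
    hi_mz: list[float] = []
    w_rt: list[float] = []
    w_mz: list[float] = []
    w_sum: list[float] = []
    home: list[tuple[int, int]] = []
    grid: dict[tuple[int, int], list[int]] = {}

    for i in order:
        r, m, w = rt[i], mz[i], intensity[i]
        ci, cj = int(math.floor(r / rt_win)), int(math.floor(m / mz_win))
        best = -1
        best_d = math.inf
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for b in grid.get((ci + di, cj + dj), ()):
                    if (
                        max(hi_rt[b], r) - min(lo_rt[b], r) <= rt_win
                        and max(hi_mz[b], m) - min(lo_mz[b], m) <= mz_win
                    ):
                        d = ((r - cent_rt[b]) / rt_win) ** 2 + (
                            (m - cent_mz[b]) / mz_win
                        ) ** 2
                        # nearest centroid; exact ties -> earliest bucket
                        if d < best_d or (d == best_d and b < best):
                            best, best_d = b, d
        if best < 0:
            best = len(cent_rt)
            cent_rt.append(r)
            cent_mz.append(m)
            lo_rt.append(r)
            hi_rt.append(r)
            lo_mz.append(m)
            hi_mz.append(m)
            w_rt.append(w * r)
            w_mz.append(w * m)
            w_sum.append(w)
            home.append((ci, cj))
            grid.setdefault((ci, cj), []).append(best)
        else:
            w_rt[best] += w * r
            w_mz[best] += w * m
            w_sum[best] += w
            cent_rt[best] = w_rt[best] / w_sum[best]
            cent_mz[best] = w_mz[best] / w_sum[best]
            lo_rt[best] = min(lo_rt[best], r)
            hi_rt[best] = max(hi_rt[best], r)
            lo_mz[best] = min(lo_mz[best], m)
            hi_mz[best] = max(hi_mz[best], m)
            cell = (
                int(math.floor(cent_rt[best] / rt_win)),
                int(math.floor(cent_mz[best] / mz_win)),
            )
            if cell != home[best]:
                grid[home[best]].remove(best)
                grid.setdefault(cell, []).append(best)
                home[best] = cell
        assign[i] = best
    return assign


def _grid_assign(
    rt: np.ndarray,
    mz: np.ndarray,
    rt_win: float,
    mz_win: float,
    rt0: float,
    mz0: float,
) -> np.ndarray:
    ii = np.floor((rt - rt0) / rt_win).astype(np.int64)
    jj = np.floor((mz - mz0) / mz_win).astype(np.int64)
    _, assign = np.unique(np.stack([ii, jj], axis=1), axis=0, return_inverse=True)
    return assign


def build_bucket_table(
    feature_lists: Sequence[FeatureList],
    rt_window: float = 0.5,
    mz_window: float = 5.0,
    mode: str = "cluster",
    rt_range: tuple[float, float] = (0.5, 17.0),
    mz_range: tuple[float, float] = (50.0, 1000.0),
) -> BucketTable:
    """Combine feature lists into a bucket table.

    Parameters
    ----------
    rt_window
        Bucket width in retention time, in **seconds** (converted to
        minutes internally; the table stores RT in minutes).
    mz_window
        Bucket width in mass, in **mDa**.
    mode
        ``"cluster"`` or ``"grid"`` (see module docstring).
    rt_range, mz_range
        Validity range in minutes / m/z; features outside are excluded
        with a logged warning (counted in ``table.qc["n_excluded"]``).
    """
    if not feature_lists:
        raise ConfigError("build_bucket_table requires at least one feature list")
    if rt_window <= 0 or mz_window <= 0:
        raise ConfigError("rt_window and mz_window must be > 0")
    if mode not in ("cluster", "grid"):
        raise ConfigError(f"mode must be 'cluster' or 'grid', got {mode!r}")

    rt_win_min = rt_window / 60.0
    mz_win_da = mz_window / 1000.0

    rts, mzs, intens, sidx = [], [], [], []
    n_excluded = 0
    for s, fl in enumerate(feature_lists):
        f = fl.features
        if not len(f):
            continue
        rt = f["rt_min"].to_numpy(float)
        mz = f["mz"].to_numpy(float)
        it = f["intensity"].to_numpy(float)
        ok = (
            (rt >= rt_range[0])
            & (rt <= rt_range[1])
            & (mz >= mz_range[0])
            & (mz <= mz_range[1])
        )
        n_bad = int((~ok).sum())
        if n_bad:
            n_excluded += n_bad
            log.warning(
                "%s: excluded %d feature(s) outside rt %s / mz %s",
                fl.sample.sample_id,
                n_bad,
                rt_range,
                mz_range,
            )
        rts.append(rt[ok])
        mzs.append(mz[ok])
        intens.append(it[ok])
        sidx.append(np.full(int(ok.sum()), s, dtype=np.int64))

    samples = samples_frame([fl.sample for fl in feature_lists])
    if not rts or sum(a.size for a in rts) == 0:
        empty = pd.DataFrame(
            np.zeros((len(feature_lists), 0)),
            index=samples.index,
            columns=pd.Index([], name="bucket_id"),
        )
        buckets = pd.DataFrame(columns=["rt_min", "mz"], index=pd.Index([], name="bucket_id"))
        return BucketTable(empty, buckets, samples, qc={"n_features": 0, "n_excluded": n_excluded, "n_same_sample_merges": 0})

    rt = np.concatenate(rts)
    mz = np.concatenate(mzs)
    intensity = np.concatenate(intens)
    sample_idx = np.concatenate(sidx)

    if mode == "cluster":
        assign = _cluster_assign(rt, mz, intensity, rt_win_min, mz_win_da)
    else:
        assign = _grid_assign(rt, mz, rt_win_min, mz_win_da, rt_range[0], mz_range[0])

    n_buckets = int(assign.max()) + 1
    w_sum = np.bincount(assign, weights=intensity, minlength=n_buckets)
    cent_rt = np.bincount(assign, weights=intensity * rt, minlength=n_buckets) / w_sum
    cent_mz = np.bincount(assign, weights=intensity * mz, minlength=n_buckets) / w_sum

    # canonical bucket order: by rt centroid, then mz centroid
    order = np.lexsort((cent_mz, cent_rt))
    rank = np.empty(n_buckets, dtype=np.int64)
    rank[order] = np.arange(n_buckets)
    assign = rank[assign]
    cent_rt, cent_mz = cent_rt[order], cent_mz[order]

    matrix = np.zeros((len(feature_lists), n_buckets))
    np.add.at(matrix, (sample_idx, assign), intensity)
    cell_count = np.zeros((len(feature_lists), n_buckets), dtype=np.int64)
    np.add.at(cell_count, (sample_idx, assign), 1)
    n_merges = int((cell_count > 1).sum())
    if n_merges:
        log.info("summed split detections in %d sample/bucket cell(s)", n_merges)

    bucket_ids = [
        f"B{k}_rt{cent_rt[k]:.4f}_mz{cent_mz[k]:.4f}" for k in range(n_buckets)
    ]
    buckets = pd.DataFrame(
        {"rt_min": cent_rt, "mz": cent_mz},
        index=pd.Index(bucket_ids, name="bucket_id"),
    )
    intens_df = pd.DataFrame(matrix, index=samples.index, columns=buckets.index)
    qc = {
        "n_features": int(rt.size),
        "n_excluded": n_excluded,
        "n_same_sample_merges": n_merges,
    }
    return BucketTable(intens_df, buckets, samples, qc=qc)


# ---------------------------------------------------------------------- I/O

def _read_csv_checked(path: str | Path, required: Sequence[str], numeric: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"{path}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: header line plus 1-based numbering
            raise ParseError(
                f"{path}:{row + 2}: non-numeric value {df[col].iloc[row]!r} in column {col!r}"
            )
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise ParseError(f"{path}:{row + 2}: missing value in column {col!r}")
        df[col] = vals
    return df


def read_feature_lists(
    feature_paths: Iterable[str | Path], metadata_path: str | Path
) -> list[FeatureList]:
    """Read per-injection feature CSVs plus the sample metadata table.

    Feature files are matched to metadata rows by file stem == sample_id.
    """
    meta = _read_csv_checked(metadata_path, SAMPLE_COLUMNS, ["replicate"])
    meta = meta.set_index("sample_id")
    lists: list[FeatureList] = []
    for path in feature_paths:
        path = Path(path)
        sample_id = path.stem
        if sample_id not in meta.index:
            raise ParseError(f"{path}: sample_id {sample_id!r} not present in {metadata_path}")
        row = meta.loc[sample_id]
        sm = SampleMeta(
            sample_id=sample_id,
            oil_id=str(row["oil_id"]),
            group=str(row["group"]),
            replicate=int(row["replicate"]),
        )
        feats = _read_csv_checked(path, ["rt_min", "mz", "intensity"], ["rt_min", "mz", "intensity"])
        lists.append(FeatureList(sample=sm, features=feats))
    return lists


_RT_SENTINEL = "#rt_min"
_MZ_SENTINEL = "#mz"


def write_bucket_table(table: BucketTable, path: str | Path) -> Path:
    """Serialise a bucket table to CSV.

    Layout: metadata columns (sample_id, oil_id, group, replicate or
    n_injections) followed by one column per bucket; the first two data
    rows (sample_id ``#rt_min`` / ``#mz``) carry the bucket centroids.
    """
    path = Path(path)
    meta_cols = list(table.samples.columns)
    head = pd.DataFrame(
        [
            [""] * len(meta_cols) + list(table.buckets["rt_min"]),
            [""] * len(meta_cols) + list(table.buckets["mz"]),
        ],
        index=pd.Index([_RT_SENTINEL, _MZ_SENTINEL], name="sample_id"),
        columns=meta_cols + list(table.buckets.index),
    )
    body = pd.concat([table.samples, table.intensities], axis=1)
    pd.concat([head, body]).to_csv(path, index_label="sample_id")
    return path


def read_bucket_table(path: str | Path) -> BucketTable:
    """Read a bucket table written by :func:`write_bucket_table`."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'sample_id'")
    df = df.set_index("sample_id")
    for sentinel in (_RT_SENTINEL, _MZ_SENTINEL):
        if sentinel not in df.index:
            raise ParseError(f"{path}: missing centroid header row {sentinel!r}")
    bucket_cols = [c for c in df.columns if c.startswith("B")]
    meta_cols = [c for c in df.columns if not c.startswith("B")]
    buckets = pd.DataFrame(
        {
            "rt_min": pd.to_numeric(df.loc[_RT_SENTINEL, bucket_cols]),
            "mz": pd.to_numeric(df.loc[_MZ_SENTINEL, bucket_cols]),
        }
    )
    buckets.index.name = "bucket_id"
    body = df.drop(index=[_RT_SENTINEL, _MZ_SENTINEL])
    samples = body[meta_cols].copy()
    for col in ("replicate", "n_injections"):
        if col in samples.columns:
            samples[col] = pd.to_numeric(samples[col]).astype(int)
    intensities = body[bucket_cols].apply(pd.to_numeric)
    intensities.columns = buckets.index
    return BucketTable(intensities, buckets, samples)
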