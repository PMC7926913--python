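"""End-to-end orchestration: simulate/read -> bucket -> filter -> select ->
model -> cross-validate -> report.

``run_pipeline`` executes the full workflow for all three variable-selection
branches (ANOVA/Tukey + correlation pruning, stepwise selection, PCA) and
both model families (multi-class LDA; one binary logit verification model
per country), writing every intermediate artifact plus a strategy-comparison
summary into a run directory.  The run directory always contains the fully
resolved configuration and seed, so any run can be reproduced exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._core import BLANK_GROUP, BucketTable, ConfigError, ORIGIN_GROUPS, log
from . import bucketing, filters, models, selection, synthdata, validation

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(d) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {unknown}")


@dataclass
class RunConfig:
    """Fully resolved parameters of one pipeline run."""

    seed: int = 0
    out_dir: str = "runs/run0"
    #: read feature lists from this directory (layout of write_feature_lists)
    #: instead of simulating, when set.
    input_dir: str | None = None
    sim: synthdata.SimConfig = field(default_factory=synthdata.SimConfig)
    # bucketing
    rt_window_s: float = 0.5
    mz_window_mda: float = 5.0
    bucket_mode: str = "cluster"
    # filter cascade
    filters: filters.FilterConfig = field(default_factory=filters.FilterConfig)
    # selection
    anova_alpha: float = 0.05
    tukey_rule: str = "any_pair"
    corr_threshold: float = 0.8
    corr_rt_window_s: float = 0.5
    stepwise_validation_frac: float = 0.25
    #: PC counts to scan; None -> derived from the filtered table's shape.
    pca_candidates: list[int] | None = None
    # cross-validation
    k_folds: int = 10
    cv_bounds: dict[str, list[int]] | None = None
    reference_mode: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        _check_keys(d, {f.name for f in fields(cls)}, "run config")
        if "sim" in d and isinstance(d["sim"], dict):
            sim = d["sim"]
            _check_keys(sim, {f.name for f in fields(synthdata.SimConfig)}, "sim config")
            for key in ("presence_prob", "intensity_log10_range", "rt_range", "mz_range"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            d["sim"] = synthdata.SimConfig(**sim)
        if "filters" in d and isinstance(d["filters"], dict):
            _check_keys(
                d["filters"], {f.name for f in fields(filters.FilterConfig)}, "filter config"
            )
            d["filters"] = filters.FilterConfig(**d["filters"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: run config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


def _pca_candidates(config: RunConfig, table: BucketTable) -> list[int]:
    if config.pca_candidates:
        return sorted(set(int(n) for n in config.pca_candidates))
    # smallest training fold has ceil(n/k) test samples removed
    n_train_min = table.n_samples - int(np.ceil(table.n_samples / config.k_folds))
    n_classes = len(table.origin_groups)
    cap = min(table.n_buckets, n_train_min - n_classes - 1)
    if cap < 1:
        raise ConfigError("too few samples/buckets for PCA-LDA")
    ns = sorted(set([1, 2, 3] + list(range(5, cap + 1, max(1, cap // 10)))))
    return [n for n in ns if n <= cap]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_file(out / "config.yaml")

    # ------------------------------------------------------------ input data
    ground_truth = None
    if config.input_dir is None:
        sim_config = config.sim
        dataset = synthdata.generate_dataset(sim_config)
        synthdata.write_feature_lists(dataset, out / "input")
        feature_lists = dataset.feature_lists
        ground_truth = dataset.ground_truth
    else:
        in_dir = Path(config.input_dir)
        paths = sorted((in_dir / "features").glob("*.csv"))
        feature_lists = bucketing.read_feature_lists(paths, in_dir / "samples.csv")

    # -------------------------------------------------------------- bucketing
    table = bucketing.build_bucket_table(
        feature_lists,
        rt_window=config.rt_window_s,
        mz_window=config.mz_window_mda,
        mode=config.bucket_mode,
    )
    bucketing.write_bucket_table(table, out / "bucket_table.csv")
    log.info("bucket table: %d samples x %d buckets", table.n_samples, table.n_buckets)

    # --------------------------------------------------------- filter cascade
    filtered, report_ = filters.run_filter_cascade(
        table, config.filters, skip_blank_stage=not table.has_blanks()
    )
    report_.to_json(out / "filter_report.json")
    bucketing.write_bucket_table(filtered, out / "filtered_table.csv")
    if filtered.n_buckets < 2:
        raise ConfigError(
            f"only {filtered.n_buckets} bucket(s) survive the filter cascade; "
            "nothing to model"
        )

    # ------------------------------------------------- selection (full data)
    sel_dir = out / "selections"
    sel_dir.mkdir(exist_ok=True)
    anova_sel = selection.anova_tukey_select(
        filtered, alpha=config.anova_alpha, rule=config.tukey_rule
    )
    anova_pruned = selection.prune_correlated(
        filtered, anova_sel, r_threshold=config.corr_threshold, rt_window=config.corr_rt_window_s
    )
    step_lda = selection.stepwise_lda_select(
        filtered, validation_split=config.stepwise_validation_frac, seed=config.seed
    )
    step_lr = {}
    for country in filtered.origin_groups:
        y = (filtered.groups == country).astype(float)
        step_lr[country] = selection.stepwise_lr_select(filtered, y, target=country)
    for name, res in [
        ("anova_tukey", anova_sel),
        ("anova_tukey_pruned", anova_pruned),
        ("stepwise_lda", step_lda),
    ] + [(f"stepwise_lr_{c}", r) for c, r in step_lr.items()]:
        with open(sel_dir / f"{name}.json", "w") as fh:
            json.dump(res.to_dict(), fh, indent=2, sort_keys=True)
        (sel_dir / f"{name}.txt").write_text("\n".join(res.selected) + "\n")

    # ------------------------------------------------------- cross-validation
    plan = validation.make_cv_plan(
        filtered.samples,
        bounds={g: tuple(b) for g, b in config.cv_bounds.items()} if config.cv_bounds else None,
        k=config.k_folds,
        seed=config.seed,
    )
    plan.to_json(out / "cv_plan.json")

    n_pc, curve = models.optimize_n_pc(
        filtered.intensities,
        filtered.groups,
        _pca_candidates(config, filtered),
        plan.iter_folds(),
    )
    curve.to_csv(out / "pca_error_curve.csv", index=False)
    log.info("optimum PC count: %d", n_pc)

    cv_dir = out / "cv"
    cv_dir.mkdir(exist_ok=True)
    results: list[validation.CVResult] = []
    anova_spec = {
        "strategy": "anova_tukey",
        "alpha": config.anova_alpha,
        "rule": config.tukey_rule,
        "prune": True,
        "r_threshold": config.corr_threshold,
        "rt_window": config.corr_rt_window_s,
    }
    lda_runs = [
        ({"kind": "lda"}, anova_spec, "lda_anova"),
        ({"kind": "lda"}, {"strategy": "stepwise_lda"}, "lda_stepwise"),
        ({"kind": "pca_lda", "n_pc": n_pc}, None, "lda_pca"),
    ]
    for model_spec, sel_spec, name in lda_runs:
        res = validation.cross_validate(
            model_spec,
            filtered,
            plan=plan,
            selection_spec=sel_spec,
            reference_mode=config.reference_mode,
            seed=config.seed,
        )
        res.to_json(cv_dir / f"{name}.json")
        results.append(res)
    for country in filtered.origin_groups:
        for sel_spec, name in [
            (anova_spec, f"lr_anova_{country}"),
            ({"strategy": "stepwise_lr"}, f"lr_stepwise_{country}"),
        ]:
            res = validation.cross_validate(
                {"kind": "lr", "target": country},
                filtered,
                plan=plan,
                selection_spec=sel_spec,
                reference_mode=config.reference_mode,
                seed=config.seed,
            )
            res.to_json(cv_dir / f"{name}.json")
            results.append(res)

    summary = validation.report(results, out / "summary.csv")

    # ----------------------------------------------------- marker recovery
    if ground_truth is not None:
        recovery = marker_recovery(
            filtered,
            ground_truth,
            {
                "anova_tukey": anova_pruned.selected,
                "stepwise_lda": step_lda.selected,
                "stepwise_lr": sorted({b for r in step_lr.values() for b in r.selected}),
            },
            rt_window_s=config.rt_window_s,
            mz_window_mda=config.mz_window_mda,
        )
        with open(out / "marker_recovery.json", "w") as fh:
            json.dump(recovery, fh, indent=2, sort_keys=True)

    log.info("run complete: %s", out)
    return out


def match_marker_buckets(
    table: BucketTable,
    ground_truth: synthdata.GroundTruth,
    rt_window_s: float = 0.5,
    mz_window_mda: float = 5.0,
) -> dict[str, str | None]:
    """Map each planted marker to the nearest bucket within one window."""
    rt_win = rt_window_s / 60.0
    mz_win = mz_window_mda / 1000.0
    out: dict[str, str | None] = {}
    b_rt = table.buckets["rt_min"].to_numpy()
    b_mz = table.buckets["mz"].to_numpy()
    for _, row in ground_truth.markers.iterrows():
        drt = np.abs(b_rt - row["rt_min"])
        dmz = np.abs(b_mz - row["mz"])
        ok = (drt <= rt_win) & (dmz <= mz_win)
        if ok.any():
            d = np.where(ok, (drt / rt_win) ** 2 + (dmz / mz_win) ** 2, np.inf)
            out[row["feature_id"]] = str(table.buckets.index[int(np.argmin(d))])
        else:
            out[row["feature_id"]] = None
    return out


def marker_recovery(
    table: BucketTable,
    ground_truth: synthdata.GroundTruth,
    selections: dict[str, list[str]],
    rt_window_s: float = 0.5,
    mz_window_mda: float = 5.0,
) -> dict:
    """Fraction of planted markers present in each strategy's selection."""
    mapping = match_marker_buckets(table, ground_truth, rt_window_s, mz_window_mda)
    marker_buckets = {b for b in mapping.values() if b is not None}
    out: dict = {
        "n_markers": len(mapping),
        "marker_buckets": sorted(marker_buckets),
        "strategies": {},
    }
    for name, sel in selections.items():
        hit = marker_buckets & set(sel)
        out["strategies"][name] = {
            "n_selected": len(sel),
            "n_markers_recovered": len(hit),
            "recovery": len(hit) / len(mapping) if mapping else float("nan"),
        }
    return out


def validate_inputs(input_dir: str | Path) -> list[str]:
    """Diagnose an input directory (features/ + samples.csv); returns messages.

    Purely diagnostic: reports missing columns, non-numeric cells, unknown
    group labels, duplicate (oil_id, replicate) pairs and feature files
    without a metadata row.  An empty list means no problems were found.
    """
    problems: list[str] = []
    input_dir = Path(input_dir)
    meta_path = input_dir / "samples.csv"
    feat_dir = input_dir / "features"
    if not meta_path.exists():
        return [f"missing metadata file {meta_path}"]
    try:
        meta = pd.read_csv(meta_path, dtype=str)
    except Exception as exc:
        return [f"{meta_path}: unreadable ({exc})"]
    for col in ("sample_id", "oil_id", "group", "replicate"):
        if col not in meta.columns:
            problems.append(f"{meta_path}: missing column {col!r}")
    if problems:
        return problems
    known = set(ORIGIN_GROUPS) | {BLANK_GROUP}
    bad_groups = sorted(set(meta["group"]) - known)
    for g in bad_groups:
        rows = [str(i + 2) for i in meta.index[meta["group"] == g]]
        problems.append(
            f"{meta_path}: unknown group {g!r} (rows {', '.join(rows)}); "
            f"expected one of {sorted(known)}"
        )
    dup = meta.duplicated(subset=["oil_id", "replicate"], keep=False)
    if dup.any():
        pairs = meta.loc[dup, ["oil_id", "replicate"]].drop_duplicates()
        for _, row in pairs.iterrows():
            problems.append(
                f"{meta_path}: duplicate (oil_id, replicate) pair "
                f"({row['oil_id']!r}, {row['replicate']!r})"
            )
    ids = set(meta["sample_id"])
    files = sorted(feat_dir.glob("*.csv")) if feat_dir.exists() else []
    if not files:
        problems.append(f"no feature files found under {feat_dir}")
    for path in files:
        if path.stem not in ids:
            problems.append(f"{path}: no metadata row for sample_id {path.stem!r}")
            continue
        try:
            bucketing._read_csv_checked(
                path, ["rt_min", "mz", "intensity"], ["rt_min", "mz", "intensity"]
            )
        except Exception as exc:
            problems.append(str(exc))
    missing_files = sorted(ids - {p.stem for p in files})
    for sid in missing_files:
        problems.append(f"{feat_dir}: no feature file for sample_id {sid!r}")
    return problems
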