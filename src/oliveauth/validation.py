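"""Country-stratified 10-fold cross-validation and classification-rate tables.

Every sample is assigned to exactly one test fold; fold sizes are 9 or 10
and the number of test samples per country is constrained per fold
(Esp 2-3, Gre 1-2, Ita 3-4, Pt 1-2 for the reference 26/13/39/17 design).
Cross-validation runs on duplicate-averaged oil rows so that the two
injections of one oil can never straddle the train/test split.

By default variable selection is repeated inside each training fold
(statistically sound).  ``reference_mode=True`` reproduces the reference
protocol of selecting once on all samples before splitting — an
information leak kept only for comparability, never the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil, floor
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from ._core import BucketTable, ConfigError, FeasibilityError, log
from . import models, selection as _selection

__all__ = [
    "REFERENCE_BOUNDS",
    "CVPlan",
    "CVResult",
    "make_cv_plan",
    "cross_validate",
    "report",
]

#: Per-country test-set bounds of the reference design.
REFERENCE_BOUNDS = {"Esp": (2, 3), "Gre": (1, 2), "Ita": (3, 4), "Pt": (1, 2)}


@dataclass
class CVPlan:
    """k test folds over the oil-level samples, respecting per-country bounds."""

    k: int
    folds: list[list[str]]
    bounds: dict[str, tuple[int, int]]
    seed: int

    @property
    def all_ids(self) -> list[str]:
        return [s for fold in self.folds for s in fold]

    def iter_folds(self) -> Iterator[tuple[list[str], list[str]]]:
        """Yield (train_ids, test_ids) per fold."""
        universe = self.all_ids
        for fold in self.folds:
            test = set(fold)
            yield [s for s in universe if s not in test], list(fold)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "folds": self.folds,
            "bounds": {g: list(b) for g, b in self.bounds.items()},
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        return path


def _random_layout(
    counts: dict[str, int],
    bounds: dict[str, tuple[int, int]],
    k: int,
    rng: np.random.Generator,
    max_tries: int = 100_000,
) -> dict[str, np.ndarray]:
    """Per-country test counts per fold, uniform over feasible layouts.

    Rejection sampling: each country's surplus above its lower bound is
    scattered uniformly over folds (respecting the per-fold gap) and the
    draw is accepted when every fold size lands on floor(N/k) or
    ceil(N/k).  Rejection keeps the per-country symmetry, so each sample
    remains uniformly assigned over folds.
    """
    total = sum(counts.values())
    lo_sizes, hi_sizes = floor(total / k), ceil(total / k)
    for g, n in counts.items():
        lo, hi = bounds[g]
        if not (k * lo <= n <= k * hi):
            raise FeasibilityError(
                f"country {g!r}: {n} samples cannot fill {k} folds within "
                f"bounds [{lo}, {hi}] ({k}x{lo}={k * lo} .. {k}x{hi}={k * hi})"
            )
    base = sum(bounds[g][0] for g in counts)
    for _ in range(max_tries):
        extras = np.zeros((k, len(counts)), dtype=int)
        for j, g in enumerate(counts):
            lo, hi = bounds[g]
            surplus = counts[g] - k * lo
            gap = hi - lo
            if surplus == 0 or gap == 0:
                continue
            if gap == 1:
                idx = rng.choice(k, size=surplus, replace=False)
                extras[idx, j] = 1
            else:
                room = np.full(k, gap)
                for _unit in range(surplus):
                    open_folds = np.flatnonzero(room > 0)
                    f = rng.choice(open_folds)
                    extras[f, j] += 1
                    room[f] -= 1
        sizes = base + extras.sum(axis=1)
        if np.all((sizes == lo_sizes) | (sizes == hi_sizes)):
            return {
                g: bounds[g][0] + extras[:, j] for j, g in enumerate(counts)
            }
    raise FeasibilityError(
        f"could not find a fold layout for counts {counts} within bounds {bounds} "
        f"and fold sizes {{{lo_sizes}, {hi_sizes}}}"
    )


def make_cv_plan(
    samples: pd.DataFrame,
    bounds: dict[str, tuple[int, int]] | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVPlan:
    """Build a constrained k-fold plan from oil-level sample metadata.

    ``samples`` is indexed by sample id with a ``group`` column (blanks,
    if present, are ignored).  ``bounds`` defaults to
    ``(floor(n_g / k), ceil(n_g / k))`` per country, which reproduces the
    reference bounds for the 26/13/39/17 design.
    """
    groups = samples["group"]
    groups = groups[groups != "Blank"]
    counts = {g: int((groups == g).sum()) for g in sorted(pd.unique(groups))}
    if not counts:
        raise ConfigError("no origin samples to assign to folds")
    if bounds is None:
        bounds = {g: (floor(n / k), ceil(n / k)) for g, n in counts.items()}
    missing = [g for g in counts if g not in bounds]
    if missing:
        raise FeasibilityError(f"bounds missing for group(s) {missing}")
    rng = np.random.default_rng(seed)
    layout = _random_layout(counts, bounds, k, rng)
    folds: list[list[str]] = [[] for _ in range(k)]
    for g in counts:
        ids = list(groups.index[groups == g])
        rng.shuffle(ids)
        start = 0
        for f in range(k):
            c = int(layout[g][f])
            folds[f].extend(ids[start : start + c])
            start += c
    return CVPlan(k=k, folds=folds, bounds={g: tuple(b) for g, b in bounds.items()}, seed=seed)


# ------------------------------------------------------------------ CV runs

@dataclass
class CVResult:
    """Aggregated train/test performance of one model x selection combination."""

    model: str
    selection: str
    target: str
    classes: list[str]
    fold_results: list[dict]
    train_rate: float = np.nan       # pooled over folds, percent
    test_rate: float = np.nan
    train_rate_foldmean: float = np.nan
    test_rate_foldmean: float = np.nan
    flagged_folds: list[int] = field(default_factory=list)
    seed: int | None = None
    reference_mode: bool = False

    def recompute_rates(self) -> tuple[float, float]:
        """Pooled rates recomputed from the stored confusion matrices."""
        totals = {"train": [0, 0], "test": [0, 0]}
        for fr in self.fold_results:
            for split in ("train", "test"):
                cm = np.asarray(fr[f"{split}_confusion"])
                totals[split][0] += int(np.trace(cm))
                totals[split][1] += int(cm.sum())
        return (
            100.0 * totals["train"][0] / totals["train"][1],
            100.0 * totals["test"][0] / totals["test"][1],
        )

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "selection": self.selection,
            "target": self.target,
            "classes": self.classes,
            "train_rate": self.train_rate,
            "test_rate": self.test_rate,
            "train_rate_foldmean": self.train_rate_foldmean,
            "test_rate_foldmean": self.test_rate_foldmean,
            "flagged_folds": self.flagged_folds,
            "seed": self.seed,
            "reference_mode": self.reference_mode,
            "folds": self.fold_results,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
        return path


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: list[str]) -> list[list[int]]:
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[str(t)], idx[str(p)]] += 1
    return cm.tolist()


def _run_selection(
    table: BucketTable, spec: dict | None, model_spec: dict, seed: int
) -> list[str]:
    if spec is None or spec.get("strategy") in (None, "none"):
        return list(table.intensities.columns)
    spec = dict(spec)
    strategy = spec.pop("strategy")
    if strategy == "anova_tukey":
        prune = spec.pop("prune", True)
        r_threshold = spec.pop("r_threshold", 0.8)
        rt_window = spec.pop("rt_window", 0.5)
        res = _selection.anova_tukey_select(table, **spec)
        if prune:
            res = _selection.prune_correlated(
                table, res, r_threshold=r_threshold, rt_window=rt_window
            )
        return res.selected
    if strategy == "stepwise_lda":
        res = _selection.stepwise_lda_select(table, seed=seed, **spec)
        return res.selected
    if strategy == "stepwise_lr":
        target = model_spec.get("target")
        if target is None:
            raise ConfigError("stepwise_lr selection requires an LR model target")
        y = (table.groups == target).astype(float)
        res = _selection.stepwise_lr_select(table, y, target=target, **spec)
        return res.selected
    raise ConfigError(f"unknown selection strategy {strategy!r}")


def _fit_predict(
    model_spec: dict,
    variables: list[str],
    train: BucketTable,
    test: BucketTable,
    y_train: pd.Series,
    y_test: pd.Series,
) -> tuple[np.ndarray, np.ndarray]:
    kind = model_spec["kind"]
    Xtr = train.intensities[variables]
    Xte = test.intensities[variables]
    if kind == "lda":
        m = models.lda_fit(Xtr, y_train)
        return (
            models.lda_predict(m, Xtr)[0].to_numpy(),
            models.lda_predict(m, Xte)[0].to_numpy(),
        )
    if kind == "pca_lda":
        n_pc = int(model_spec["n_pc"])
        pca = models.pca_fit(Xtr, n_pc)
        m = models.lda_fit(models.pca_transform(pca, Xtr), y_train)
        return (
            models.lda_predict(m, models.pca_transform(pca, Xtr))[0].to_numpy(),
            models.lda_predict(m, models.pca_transform(pca, Xte))[0].to_numpy(),
        )
    if kind == "lr":
        m = models.lr_fit(
            Xtr,
            y_train.to_numpy(float),
            target=model_spec.get("target", "target"),
            threshold=model_spec.get("threshold", 0.5),
        )
        return (
            models.lr_predict(m, Xtr)["verdict"].astype(int).to_numpy().astype(str),
            models.lr_predict(m, Xte)["verdict"].astype(int).to_numpy().astype(str),
        )
    raise ConfigError(f"unknown model kind {kind!r}")


def cross_validate(
    model_spec: dict,
    table: BucketTable,
    labels: pd.Series | None = None,
    plan: CVPlan | None = None,
    selection_spec: dict | None = None,
    reference_mode: bool = False,
    seed: int = 0,
) -> CVResult:
    """Run the constrained k-fold CV for one model/selection combination.

    ``model_spec`` examples: ``{"kind": "lda"}``,
    ``{"kind": "pca_lda", "n_pc": 5}``, ``{"kind": "lr", "target": "Ita"}``.
    ``selection_spec`` examples: ``None`` (use all variables),
    ``{"strategy": "anova_tukey", "alpha": 0.05, "prune": True}``,
    ``{"strategy": "stepwise_lda"}``, ``{"strategy": "stepwise_lr"}``.

    Selection (and PCA, and the model fit) happens inside each training
    fold; with ``reference_mode=True`` the selection alone is computed once on
    the full table first.
    """
    work = table.drop_blanks()
    y_all = (labels if labels is not None else work.groups).astype(str)
    if plan is None:
        plan = make_cv_plan(work.samples, seed=seed)
    kind = model_spec["kind"]
    target = str(model_spec.get("target", "all"))
    if kind == "lr":
        y_all = pd.Series(
            (y_all == target).astype(int).astype(str), index=y_all.index
        )
        classes = ["0", "1"]
    else:
        classes = sorted(pd.unique(y_all))

    shared_vars: list[str] | None = None
    if reference_mode:
        shared_vars = _run_selection(work, selection_spec, model_spec, seed)

    fold_results = []
    flagged = []
    tr_ok = tr_n = te_ok = te_n = 0
    tr_rates = []
    te_rates = []
    for f, (train_ids, test_ids) in enumerate(plan.iter_folds()):
        train = work.subset_samples(train_ids)
        test = work.subset_samples(test_ids)
        y_tr, y_te = y_all.loc[train_ids], y_all.loc[test_ids]
        if kind == "lr" and (y_tr.nunique() < 2 or y_te.nunique() < 1):
            flagged.append(f)
            log.warning("fold %d skipped for LR target %s: single-class labels", f, target)
            continue
        if shared_vars is not None:
            variables = shared_vars
        else:
            variables = _run_selection(train, selection_spec, model_spec, seed)
        if not variables and kind != "lr":
            flagged.append(f)
            log.warning("fold %d skipped: selection returned no variables", f)
            continue
        # an empty LR selection is a legitimate BIC outcome: the model
        # degrades to intercept-only and predicts the majority verdict
        pred_tr, pred_te = _fit_predict(model_spec, variables, train, test, y_tr, y_te)
        cm_tr = _confusion(y_tr.to_numpy(), pred_tr, classes)
        cm_te = _confusion(y_te.to_numpy(), pred_te, classes)
        ok_tr = int(np.trace(cm_tr))
        ok_te = int(np.trace(cm_te))
        tr_ok += ok_tr
        tr_n += len(train_ids)
        te_ok += ok_te
        te_n += len(test_ids)
        tr_rates.append(100.0 * ok_tr / len(train_ids))
        te_rates.append(100.0 * ok_te / len(test_ids))
        fold_results.append(
            {
                "fold": f,
                "n_train": len(train_ids),
                "n_test": len(test_ids),
                "n_variables": len(variables),
                "variables": list(variables),
                "train_confusion": cm_tr,
                "test_confusion": cm_te,
            }
        )
    if te_n == 0:
        raise ConfigError("every fold was flagged; cannot compute rates")
    sel_name = (selection_spec or {}).get("strategy") or "none"
    result = CVResult(
        model=kind,
        selection=sel_name,
        target=target,
        classes=classes,
        fold_results=fold_results,
        train_rate=100.0 * tr_ok / tr_n,
        test_rate=100.0 * te_ok / te_n,
        train_rate_foldmean=float(np.mean(tr_rates)),
        test_rate_foldmean=float(np.mean(te_rates)),
        flagged_folds=flagged,
        seed=plan.seed,
        reference_mode=reference_mode,
    )
    log.info(
        "CV %s/%s target=%s: train %.1f%%, test %.1f%%",
        kind,
        sel_name,
        target,
        result.train_rate,
        result.test_rate,
    )
    return result


def report(
    results: Sequence[CVResult], path: str | Path | None = None
) -> pd.DataFrame:
    """Render train/test correct-classification rates as a tidy table.

    One row per result with the model, selection strategy, target and the
    pooled train/test rates (percent); fold-mean rates are included as
    secondary columns.  When ``path`` is given the table is written as CSV
    and a human-readable text rendering as ``path`` + ``.txt``.
    """
    if not results:
        raise ConfigError("report requires at least one CVResult")
    rows = [
        {
            "model": r.model,
            "selection": r.selection,
            "target": r.target,
            "train_rate": round(r.train_rate, 1),
            "test_rate": round(r.test_rate, 1),
            "train_rate_foldmean": round(r.train_rate_foldmean, 1),
            "test_rate_foldmean": round(r.test_rate_foldmean, 1),
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if path is not None:
        path = Path(path)
        df.to_csv(path, index=False)
        lines = ["Overall correct classification rate (%)", ""]
        lines.append(df.to_string(index=False))
        lr = df[df["model"] == "lr"]
        if len(lr):
            pivot = lr.pivot_table(
                index="selection", columns="target", values=["train_rate", "test_rate"]
            )
            lines += ["", "Binary LR verification models by country:", pivot.to_string()]
        Path(str(path) + ".txt").write_text("\n".join(lines) + "\n")
    return df
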