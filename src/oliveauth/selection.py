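"""Variable-selection strategies for the origin classifiers.

Three routes to a small, predictive variable set are provided:

* :func:`anova_tukey_select` — univariate screen: per bucket, all-pairs
  Tukey HSD (Tukey-Kramer for the unbalanced 26/13/39/17 design) keeps a
  bucket when group means differ significantly; usually followed by
  :func:`prune_correlated`, which drops one of any pair of co-eluting
  (same retention time) buckets with |Pearson r| > 0.8.
* :func:`stepwise_lda_select` — greedy forward selection for multi-class
  LDA, sized by the validation-set entropy R^2 (McFadden's pseudo-R^2 of
  the LDA posteriors).
* :func:`stepwise_lr_select` — greedy forward selection for a binary
  country-vs-rest logit model with the Bayesian information criterion as
  the stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

from ._core import BucketTable, ConfigError, log
from . import models

__all__ = [
    "SelectionResult",
    "tukey_screen",
    "anova_tukey_select",
    "prune_correlated",
    "stepwise_lda_select",
    "stepwise_lr_select",
]


@dataclass
class SelectionResult:
    """Ordered retained variables plus the per-step criterion trace."""

    strategy: str
    target: str
    selected: list[str]
    #: one criterion value per selected variable (min Tukey p for the
    #: univariate screen, validation entropy R^2 per step for stepwise
    #: LDA, BIC after each addition for stepwise LR)
    trace: list[float] = field(default_factory=list)
    #: optional per-step detail table (stepwise strategies)
    details: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ConfigError("selection contains duplicate bucket ids")

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "target": self.target,
            "selected": list(self.selected),
            "trace": [float(t) for t in self.trace],
        }


# ------------------------------------------------------- ANOVA/Tukey screen

def tukey_screen(
    X: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    rule: str = "any_pair",
) -> pd.DataFrame:
    """Vectorised all-pairs Tukey HSD over every column of ``X``.

    Returns a DataFrame indexed like ``X.columns`` with the keep decision,
    the largest pairwise studentized-range statistic, the one-way ANOVA
    p-value, and (for kept buckets) the smallest Tukey-adjusted p-value.

    ``rule="any_pair"``: keep when any two group means differ
    significantly.  ``rule="two_plus"``: keep when some group differs
    significantly from at least two other groups.

    Columns with zero pooled within-group variance are decided by exact
    equality of the group means (a "difference" is any nonzero one) and
    logged.
    """
    if rule not in ("any_pair", "two_plus"):
        raise ConfigError(f"rule must be 'any_pair' or 'two_plus', got {rule!r}")
    levels = sorted(pd.unique(groups))
    k = len(levels)
    if k < 2:
        raise ConfigError("Tukey screen requires at least two groups")
    mats = [X.loc[(groups == g).to_numpy()].to_numpy(float) for g in levels]
    ns = np.array([m.shape[0] for m in mats])
    if (ns < 2).any():
        raise ConfigError("every group needs >= 2 samples for the Tukey screen")
    n_total = int(ns.sum())
    df = n_total - k
    means = np.stack([m.mean(axis=0) for m in mats])            # k x p
    sse = np.stack([((m - m.mean(axis=0)) ** 2).sum(axis=0) for m in mats]).sum(axis=0)
    msw = sse / df

    pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
    q = np.zeros((len(pairs), X.shape[1]))
    diff = np.zeros_like(q, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, (a, b) in enumerate(pairs):
            se = np.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q[i] = np.abs(means[a] - means[b]) / se
            diff[i] = means[a] != means[b]

    q_crit = studentized_range.ppf(1 - alpha, k, df)
    degenerate = msw == 0
    sig = np.where(degenerate[None, :], diff, q > q_crit)
    if degenerate.any():
        log.info(
            "Tukey screen: %d bucket(s) with zero within-group variance decided "
            "by exact equality of group means",
            int(degenerate.sum()),
        )

    if rule == "any_pair":
        keep = sig.any(axis=0)
    else:
        partners = np.zeros((k, X.shape[1]))
        for i, (a, b) in enumerate(pairs):
            partners[a] += sig[i]
            partners[b] += sig[i]
        keep = (partners >= 2).any(axis=0)

    grand = (ns @ means) / n_total
    ssb = (ns[:, None] * (means - grand) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / msw
    anova_p = np.where(degenerate, np.where(ssb > 0, 0.0, 1.0), f_dist.sf(F, k - 1, df))

    max_q = q.max(axis=0)
    min_p = np.full(X.shape[1], np.nan)
    idx = np.flatnonzero(keep & ~degenerate)
    if idx.size:
        min_p[idx] = studentized_range.sf(max_q[idx], k, df)
    min_p[keep & degenerate] = 0.0
    return pd.DataFrame(
        {"keep": keep, "max_q": max_q, "min_tukey_p": min_p, "anova_p": anova_p},
        index=X.columns,
    )


def anova_tukey_select(
    table: BucketTable,
    alpha: float = 0.05,
    rule: str = "any_pair",
    labels: pd.Series | None = None,
) -> SelectionResult:
    """Keep buckets whose group means differ per Tukey HSD at level ``alpha``.

    Runs on the (duplicate-averaged) origin samples of ``table``; blanks
    are ignored.  Selected buckets are ordered by increasing Tukey p.
    """
    work = table.drop_blanks()
    y = labels if labels is not None else work.groups
    stats = tukey_screen(work.intensities, y, alpha=alpha, rule=rule)
    kept = stats[stats["keep"]].sort_values(["min_tukey_p", "max_q"], ascending=[True, False])
    result = SelectionResult(
        strategy="anova_tukey",
        target="all",
        selected=list(kept.index),
        trace=[float(p) for p in kept["min_tukey_p"]],
        details=stats,
    )
    log.info("ANOVA/Tukey screen kept %d of %d buckets", len(result.selected), table.n_buckets)
    return result


def prune_correlated(
    table: BucketTable,
    selected: SelectionResult | Sequence[str],
    r_threshold: float = 0.8,
    rt_window: float = 0.5,
) -> SelectionResult:
    """Drop redundant co-eluting buckets from a selection.

    Among selected buckets whose RT centroids lie within ``rt_window``
    seconds of each other, any pair with |Pearson r| > ``r_threshold``
    across samples is reduced to one representative: the bucket with the
    larger grand-mean intensity (ties -> lower bucket id).  Idempotent;
    every surviving same-RT pair satisfies |r| <= ``r_threshold``.
    """
    if isinstance(selected, SelectionResult):
        ids, strategy, target = list(selected.selected), selected.strategy, selected.target
        trace = dict(zip(selected.selected, selected.trace)) if selected.trace else {}
    else:
        ids, strategy, target, trace = list(selected), "manual", "all", {}
    missing = [b for b in ids if b not in table.buckets.index]
    if missing:
        raise ConfigError(f"selected bucket(s) not in table: {missing[:3]}")
    work = table.drop_blanks()
    rt = table.buckets["rt_min"]
    win_min = rt_window / 60.0
    grand = work.intensities[ids].mean(axis=0)
    pos = {b: i for i, b in enumerate(table.buckets.index)}
    order = sorted(ids, key=lambda b: (-grand[b], pos[b]))
    kept: list[str] = []
    X = work.intensities
    for b in order:
        redundant = False
        for kb in kept:
            if abs(rt[b] - rt[kb]) <= win_min:
                r = np.corrcoef(X[b], X[kb])[0, 1]
                if np.isfinite(r) and abs(r) > r_threshold:
                    redundant = True
                    break
        if not redundant:
            kept.append(b)
    kept_set = set(kept)
    surviving = [b for b in ids if b in kept_set]
    log.info("correlation pruning: %d -> %d buckets", len(ids), len(surviving))
    return SelectionResult(
        strategy=strategy,
        target=target,
        selected=surviving,
        trace=[trace[b] for b in surviving] if trace else [],
    )


# ----------------------------------------------------------- stepwise LDA

def _stratified_holdout(
    y: pd.Series, frac: float, seed: int
) -> tuple[pd.Index, pd.Index]:
    rng = np.random.default_rng(seed)
    val = []
    for g in sorted(pd.unique(y)):
        ids = list(y.index[y == g])
        rng.shuffle(ids)
        n_val = max(1, int(round(frac * len(ids))))
        if n_val >= len(ids) - 1:
            raise ConfigError(
                f"validation fraction {frac} leaves fewer than 2 training samples "
                f"for group {g!r}"
            )
        val.extend(ids[:n_val])
    val_idx = pd.Index(val)
    train_idx = y.index.difference(val_idx, sort=False)
    return train_idx, val_idx


def _wilks_lambda(X: np.ndarray, y: np.ndarray) -> float:
    levels = np.unique(y)
    grand = X.mean(axis=0)
    T = (X - grand).T @ (X - grand)
    W = np.zeros_like(T)
    for g in levels:
        rows = X[y == g]
        d = rows - rows.mean(axis=0)
        W += d.T @ d
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_t <= 0:
        return 1.0
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def stepwise_lda_select(
    table: BucketTable,
    labels: pd.Series | None = None,
    max_vars: int | None = None,
    validation_split: float | Sequence[str] = 0.25,
    seed: int = 0,
) -> SelectionResult:
    """Forward stepwise selection for multi-class LDA.

    Each step adds the candidate minimising training misclassification
    (ties -> larger Wilks' lambda reduction); the search stops when no
    candidate keeps the training error from rising (or at ``max_vars``).
    The returned size is the step maximising the validation entropy R^2,
    with validation misclassification, then smaller size, as tie-breakers.
    """
    work = table.drop_blanks()
    y = (labels if labels is not None else work.groups).astype(str)
    if isinstance(validation_split, float):
        train_idx, val_idx = _stratified_holdout(y, validation_split, seed)
    else:
        val_idx = pd.Index(list(validation_split))
        train_idx = y.index.difference(val_idx, sort=False)
    X = work.intensities
    Xtr, ytr = X.loc[train_idx], y.loc[train_idx]
    Xva, yva = X.loc[val_idx], y.loc[val_idx]
    candidates = list(X.columns)
    n_classes = ytr.nunique()
    cap = min(
        len(candidates),
        len(train_idx) - n_classes - 1,
        max_vars if max_vars is not None else 30,
    )

    selected: list[str] = []
    records = []
    current_err = np.inf
    n_skipped = 0
    while len(selected) < cap:
        best = None
        for v in candidates:
            cols = selected + [v]
            try:
                model = models.lda_fit(Xtr[cols], ytr)
            except models.SingularCovarianceError:
                n_skipped += 1
                continue
            pred, _ = models.lda_predict(model, Xtr[cols])
            err = float((pred.to_numpy() != ytr.to_numpy()).mean())
            lam = _wilks_lambda(Xtr[cols].to_numpy(float), ytr.to_numpy())
            if best is None or (err, lam) < (best[1], best[2]):
                best = (v, err, lam, model)
        if best is None or best[1] > current_err:
            break
        v, err, lam, model = best
        selected.append(v)
        candidates.remove(v)
        current_err = err
        cols = list(selected)
        val_pred, _ = models.lda_predict(model, Xva[cols])
        val_err = float((val_pred.to_numpy() != yva.to_numpy()).mean())
        val_r2 = models.lda_entropy_r2(model, Xva[cols], yva)
        records.append(
            {
                "step": len(selected),
                "variable": v,
                "train_misclass": err,
                "wilks_lambda": lam,
                "val_misclass": val_err,
                "val_entropy_r2": val_r2,
            }
        )
    if n_skipped:
        log.info("stepwise LDA skipped %d singular candidate fit(s)", n_skipped)
    if not records:
        return SelectionResult("stepwise_lda", "all", [], [], details=pd.DataFrame())
    path = pd.DataFrame(records)
    best_row = path.sort_values(
        ["val_entropy_r2", "val_misclass", "step"], ascending=[False, True, True]
    ).iloc[0]
    size = int(best_row["step"])
    chosen = selected[:size]
    log.info(
        "stepwise LDA: %d steps explored, size %d chosen (val entropy R^2 = %.3f)",
        len(path),
        size,
        best_row["val_entropy_r2"],
    )
    return SelectionResult(
        strategy="stepwise_lda",
        target="all",
        selected=chosen,
        trace=[float(r) for r in path["val_entropy_r2"].iloc[:size]],
        details=path,
    )


# ------------------------------------------------------------ stepwise LR

def stepwise_lr_select(
    table: BucketTable,
    binary_labels: pd.Series | np.ndarray,
    target: str = "target",
    max_vars: int | None = None,
) -> SelectionResult:
    """Forward stepwise selection for a binary logit model, BIC stopping rule.

    Starting from the intercept-only model, each step adds the variable
    with the largest BIC decrease and stops when no addition decreases
    BIC.  The trace holds the BIC after each accepted addition and is
    strictly decreasing.
    """
    work = table.drop_blanks()
    X = work.intensities
    y = np.asarray(binary_labels, float)
    if len(y) != len(X):
        raise ConfigError("binary_labels length does not match the table's samples")
    null = models.lr_fit(X[[]], y, target=target)
    current_bic = null.bic
    candidates = list(X.columns)
    cap = min(len(candidates), max_vars if max_vars is not None else len(candidates))
    selected: list[str] = []
    trace: list[float] = []
    while len(selected) < cap:
        best = None
        for v in candidates:
            try:
                fit = models.lr_fit(X[selected + [v]], y, target=target)
            except ConfigError:
                continue
            if best is None or fit.bic < best[1].bic:
                best = (v, fit)
        if best is None or best[1].bic >= current_bic - 1e-9:
            break
        v, fit = best
        selected.append(v)
        candidates.remove(v)
        current_bic = fit.bic
        trace.append(float(fit.bic))
    log.info("stepwise LR (%s): selected %d variable(s), BIC %.2f", target, len(selected), current_bic)
    return SelectionResult(strategy="stepwise_lr", target=target, selected=selected, trace=trace)
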