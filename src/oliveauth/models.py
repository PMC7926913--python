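"""Classification models: pooled-covariance LDA, PCA(-LDA) and binary logit.

LDA is the classical Gaussian classifier with class means, one pooled
within-class covariance and class priors; the discriminant is linear and
the posterior of class ``k`` for a row ``x`` is

    P(k | x)  proportional to  pi_k * exp(-1/2 (x - mu_k)' Sigma^-1 (x - mu_k)).

PCA is mean-centred principal components (delegated to scikit-learn's
exact SVD solver) used to compress more variables than samples before
LDA.  The binary logit model is fit by iteratively reweighted least
squares (IRLS); when the classes are perfectly separable the unpenalised
likelihood has no maximiser, so the fit falls back to a tiny ridge
penalty (1e-6 on the standardised coefficients, never the intercept) and
raises a ``separation`` flag — verdicts are essentially unchanged but the
coefficients stay finite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.decomposition import PCA as _SKPCA

from ._core import ConfigError, ParseError, SingularCovarianceError, log

__all__ = [
    "LDAModel",
    "PCAModel",
    "LRModel",
    "lda_fit",
    "lda_predict",
    "pca_fit",
    "pca_transform",
    "optimize_n_pc",
    "lr_fit",
    "lr_predict",
    "save_model",
    "load_model",
]

_EPS = 1e-15


def _as_matrix(X, variables: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        if variables is not None:
            X = X.loc[:, list(variables)]
        return X.to_numpy(float), list(X.columns)
    arr = np.asarray(X, float)
    if arr.ndim == 1:
        arr = arr[:, None]
    names = list(variables) if variables is not None else [f"x{i}" for i in range(arr.shape[1])]
    return arr, names


# ======================================================================= LDA

@dataclass
class LDAModel:
    classes: list[str]
    means: pd.DataFrame          # classes x variables
    pooled_cov: np.ndarray       # variables x variables
    priors: pd.Series            # per class, sums to 1
    variables: list[str]
    _cov_inv: np.ndarray = field(repr=False, default=None)


def lda_fit(X, y, priors: pd.Series | dict | None = None) -> LDAModel:
    """Fit Gaussian LDA with a pooled within-class covariance.

    Priors default to the training class frequencies (the reference design
    is unbalanced); pass a mapping for e.g. uniform priors.
    """
    Xm, variables = _as_matrix(X)
    y = pd.Series(np.asarray(y), name="class")
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ConfigError("lda_fit requires at least two classes")
    n, p = Xm.shape
    if n <= p:
        raise SingularCovarianceError(
            f"LDA needs more samples than variables for a nonsingular pooled "
            f"covariance (n={n}, p={p}); reduce variables by selection or PCA first"
        )
    means = np.zeros((len(classes), p))
    scatter = np.zeros((p, p))
    for k, c in enumerate(classes):
        rows = Xm[(y == c).to_numpy()]
        if len(rows) < 1:
            raise ConfigError(f"class {c!r} has no samples")
        means[k] = rows.mean(axis=0)
        d = rows - means[k]
        scatter += d.T @ d
    cov = scatter / (n - len(classes))
    try:
        cov_inv = np.linalg.inv(cov)
        # reject numerically singular matrices that inv() silently "solves"
        if np.linalg.cond(cov) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError as exc:
        raise SingularCovarianceError(
            f"pooled covariance is singular for p={p} variables at n={n} samples"
        ) from exc
    if priors is None:
        pr = y.value_counts(normalize=True).reindex(classes)
    else:
        pr = pd.Series(priors, dtype=float).reindex(classes)
        if pr.isna().any() or not np.isclose(pr.sum(), 1.0):
            raise ConfigError("priors must cover every class and sum to 1")
    return LDAModel(
        classes=[str(c) for c in classes],
        means=pd.DataFrame(means, index=[str(c) for c in classes], columns=variables),
        pooled_cov=cov,
        priors=pr.set_axis([str(c) for c in classes]),
        variables=variables,
        _cov_inv=cov_inv,
    )


def _lda_log_posteriors(model: LDAModel, Xm: np.ndarray) -> np.ndarray:
    ci = model._cov_inv
    if ci is None:
        ci = np.linalg.inv(model.pooled_cov)
    logp = np.empty((Xm.shape[0], len(model.classes)))
    for k in range(len(model.classes)):
        d = Xm - model.means.to_numpy()[k]
        logp[:, k] = -0.5 * np.einsum("ij,jk,ik->i", d, ci, d) + np.log(
            model.priors.iloc[k]
        )
    return logp


def lda_predict(model: LDAModel, X) -> tuple[pd.Series, pd.DataFrame]:
    """Predicted class labels and normalised posterior probabilities."""
    Xm, _ = _as_matrix(X, model.variables)
    logp = _lda_log_posteriors(model, Xm)
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    post /= post.sum(axis=1, keepdims=True)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Xm))
    posteriors = pd.DataFrame(post, index=index, columns=model.classes)
    labels = posteriors.idxmax(axis=1)
    return labels, posteriors


def lda_entropy_r2(model: LDAModel, X, y) -> float:
    """McFadden's pseudo-R^2, 1 - l(model)/l(null), of LDA posteriors on (X, y).

    The null model predicts the training priors for every row.  1 means
    perfect (posterior 1 on the true class everywhere), 0 no better than
    the priors.
    """
    _, post = lda_predict(model, X)
    y = np.asarray(y, dtype=str)
    p_true = np.clip(post.to_numpy()[np.arange(len(y)), [model.classes.index(c) for c in y]], _EPS, 1.0)
    ll = np.log(p_true).sum()
    p_null = np.clip(model.priors.reindex(y).to_numpy(), _EPS, 1.0)
    ll0 = np.log(p_null).sum()
    if ll0 == 0.0:
        return 1.0 if ll == 0.0 else -np.inf
    return float(1.0 - ll / ll0)


# ======================================================================= PCA

@dataclass
class PCAModel:
    mean: np.ndarray
    components: np.ndarray               # n_pc x p, orthonormal rows
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    n_pc: int
    variables: list[str]


def pca_fit(X, n_pc: int) -> PCAModel:
    """Mean-centred PCA with ``n_pc`` components (exact SVD)."""
    Xm, variables = _as_matrix(X)
    n, p = Xm.shape
    limit = min(n - 1, p)
    if not 1 <= n_pc <= limit:
        raise ConfigError(
            f"n_pc must lie in [1, min(n_samples - 1, n_variables)] = [1, {limit}], got {n_pc}"
        )
    sk = _SKPCA(n_components=n_pc, svd_solver="full")
    sk.fit(Xm)
    return PCAModel(
        mean=sk.mean_,
        components=sk.components_,
        explained_variance=sk.explained_variance_,
        explained_variance_ratio=sk.explained_variance_ratio_,
        n_pc=n_pc,
        variables=variables,
    )


def pca_transform(model: PCAModel, X) -> pd.DataFrame:
    """Project rows onto the fitted components; columns PC1..PCn."""
    Xm, _ = _as_matrix(X, model.variables)
    scores = (Xm - model.mean) @ model.components.T
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Xm))
    return pd.DataFrame(scores, index=index, columns=[f"PC{i + 1}" for i in range(model.n_pc)])


def optimize_n_pc(
    X,
    y,
    candidate_ns: Sequence[int],
    folds: Iterable[tuple[Sequence, Sequence]],
) -> tuple[int, pd.DataFrame]:
    """Pick the PC count minimising cross-validated PCA-LDA test error.

    For every candidate the PCA (and the LDA on its scores) is refit on
    each fold's training rows only.  Returns the argmin (ties -> smaller
    count) and the full error curve for plotting.
    """
    if not len(candidate_ns):
        raise ConfigError("candidate_ns must be nonempty")
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, float))
    y = pd.Series(np.asarray(y, dtype=str), index=X.index)
    folds = list(folds)
    errors = []
    for n_pc in candidate_ns:
        wrong = total = 0
        for train_ids, test_ids in folds:
            Xtr, Xte = X.loc[list(train_ids)], X.loc[list(test_ids)]
            pca = pca_fit(Xtr, n_pc)
            lda = lda_fit(pca_transform(pca, Xtr), y.loc[list(train_ids)])
            pred, _ = lda_predict(lda, pca_transform(pca, Xte))
            wrong += int((pred.to_numpy() != y.loc[list(test_ids)].to_numpy()).sum())
            total += len(test_ids)
        errors.append(wrong / total)
    curve = pd.DataFrame({"n_pc": list(candidate_ns), "cv_error": errors})
    best = int(curve.loc[curve["cv_error"].idxmin(), "n_pc"])
    # idxmin already returns the first (smallest n_pc) minimum if sorted;
    # enforce it regardless of candidate order
    mmin = curve["cv_error"].min()
    best = int(curve.loc[curve["cv_error"] == mmin, "n_pc"].min())
    return best, curve


# ==================================================================== logit

@dataclass
class LRModel:
    target: str
    variables: list[str]
    intercept: float
    coef: np.ndarray
    threshold: float = 0.5
    loglik: float = np.nan
    bic: float = np.nan
    n_iter: int = 0
    converged: bool = False
    separation: bool = False
    ridge: float = 0.0


def _irls(
    Xd: np.ndarray, y: np.ndarray, ridge: float, max_iter: int, tol: float
) -> tuple[np.ndarray, int, bool]:
    n, p1 = Xd.shape
    beta = np.zeros(p1)
    ybar = min(max(y.mean(), 1e-3), 1 - 1e-3)
    beta[0] = np.log(ybar / (1 - ybar))
    pen = np.eye(p1) * ridge
    pen[0, 0] = 0.0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xd @ beta, -30, 30)
        mu = expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        z = eta + (y - mu) / w
        XtW = Xd.T * w
        beta_new = np.linalg.solve(XtW @ Xd + pen, XtW @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            return beta, it, True
        if np.max(np.abs(beta)) > 1e6:
            break
    return beta, it, False


def lr_fit(
    X,
    y,
    variables: Sequence[str] | None = None,
    threshold: float = 0.5,
    ridge: float = 0.0,
    auto_ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
    target: str = "target",
) -> LRModel:
    """Maximum-likelihood binary logistic fit by IRLS.

    Predictors are standardised internally for numerical stability (the
    MLE is unaffected; coefficients are reported on the original scale).
    On perfect separation — IRLS fails to converge or the normal
    equations become singular — the fit is repeated with the small
    ``auto_ridge`` penalty on the standardised slopes and flagged.
    """
    Xm, names = _as_matrix(X, variables)
    y = np.asarray(y, float)
    uy = np.unique(y)
    if not np.isin(uy, (0.0, 1.0)).all() or len(uy) < 2:
        raise ConfigError("lr_fit requires binary labels in {0, 1} with both classes present")
    n, p = Xm.shape
    mu = Xm.mean(axis=0) if p else np.zeros(0)
    sd = Xm.std(axis=0, ddof=0) if p else np.zeros(0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (Xm - mu) / sd
    Xd = np.column_stack([np.ones(n), Xs])

    separation = False
    used_ridge = ridge
    try:
        beta, n_iter, converged = _irls(Xd, y, ridge, max_iter, tol)
        if not converged:
            raise np.linalg.LinAlgError("IRLS did not converge")
        # a finite MLE neither reproduces the labels exactly nor needs a
        # standardised slope of 30 log-odds per SD; either means the
        # optimiser ran off toward a separating hyperplane
        if ridge == 0.0 and p:
            resid = np.abs(y - expit(np.clip(Xd @ beta, -30, 30)))
            if np.all(resid < 1e-5) or np.max(np.abs(beta[1:])) > 30.0:
                raise np.linalg.LinAlgError("perfect separation")
    except np.linalg.LinAlgError:
        separation = True
        used_ridge = max(ridge, auto_ridge)
        beta, n_iter, converged = _irls(Xd, y, used_ridge, max_iter, tol)
        if not converged:
            raise ConfigError(
                f"logistic fit did not converge within {max_iter} IRLS iterations "
                f"even with ridge {used_ridge:g}"
            )
        log.info("perfect separation detected; refit with ridge %g", used_ridge)

    coef = beta[1:] / sd
    intercept = float(beta[0] - (mu * coef).sum())
    eta = np.clip(intercept + Xm @ coef, -700, 700)
    prob = np.clip(expit(eta), _EPS, 1 - _EPS)
    loglik = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    bic = float(-2 * loglik + (p + 1) * np.log(n))
    return LRModel(
        target=target,
        variables=names,
        intercept=intercept,
        coef=coef,
        threshold=threshold,
        loglik=loglik,
        bic=bic,
        n_iter=n_iter,
        converged=converged,
        separation=separation,
        ridge=used_ridge,
    )


def lr_predict(model: LRModel, X) -> pd.DataFrame:
    """Per-row probability of the target class and yes/no verdict."""
    Xm, _ = _as_matrix(X, model.variables)
    eta = np.clip(model.intercept + Xm @ model.coef, -700, 700)
    prob = np.clip(expit(eta), _EPS, 1 - _EPS)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(Xm))
    return pd.DataFrame(
        {"probability": prob, "verdict": prob >= model.threshold}, index=index
    )


# ============================================================ serialisation

def save_model(model, path: str | Path) -> Path:
    """Serialise an LDAModel / PCAModel / LRModel to JSON."""
    path = Path(path)
    if isinstance(model, LDAModel):
        obj = {
            "kind": "lda",
            "classes": model.classes,
            "means": model.means.to_numpy().tolist(),
            "pooled_cov": model.pooled_cov.tolist(),
            "priors": model.priors.to_list(),
            "variables": model.variables,
        }
    elif isinstance(model, PCAModel):
        obj = {
            "kind": "pca",
            "mean": model.mean.tolist(),
            "components": model.components.tolist(),
            "explained_variance": model.explained_variance.tolist(),
            "explained_variance_ratio": model.explained_variance_ratio.tolist(),
            "n_pc": model.n_pc,
            "variables": model.variables,
        }
    elif isinstance(model, LRModel):
        obj = {
            "kind": "lr",
            "target": model.target,
            "variables": model.variables,
            "intercept": model.intercept,
            "coef": model.coef.tolist(),
            "threshold": model.threshold,
            "loglik": model.loglik,
            "bic": model.bic,
            "separation": model.separation,
            "ridge": model.ridge,
        }
    else:
        raise ConfigError(f"cannot serialise model of type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
    return path


def load_model(path: str | Path):
    with open(path) as fh:
        obj = json.load(fh)
    kind = obj.get("kind")
    if kind == "lda":
        means = pd.DataFrame(obj["means"], index=obj["classes"], columns=obj["variables"])
        return LDAModel(
            classes=obj["classes"],
            means=means,
            pooled_cov=np.asarray(obj["pooled_cov"]),
            priors=pd.Series(obj["priors"], index=obj["classes"]),
            variables=obj["variables"],
            _cov_inv=np.linalg.inv(np.asarray(obj["pooled_cov"])),
        )
    if kind == "pca":
        return PCAModel(
            mean=np.asarray(obj["mean"]),
            components=np.asarray(obj["components"]),
            explained_variance=np.asarray(obj["explained_variance"]),
            explained_variance_ratio=np.asarray(obj["explained_variance_ratio"]),
            n_pc=obj["n_pc"],
            variables=obj["variables"],
        )
    if kind == "lr":
        return LRModel(
            target=obj["target"],
            variables=obj["variables"],
            intercept=obj["intercept"],
            coef=np.asarray(obj["coef"]),
            threshold=obj["threshold"],
            loglik=obj["loglik"],
            bic=obj["bic"],
            separation=obj["separation"],
            ridge=obj["ridge"],
        )
    raise ParseError(f"{path}: unknown model kind {kind!r}")
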