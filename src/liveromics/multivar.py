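"""Multivariate statistics: PCA, Ward clustering, OPLS-DA and co-inertia.

OPLS-DA follows the NIPALS orthogonal-projection scheme: one predictive
component against the +/-1 class code plus k orthogonal (class-unrelated)
components, k selected by leave-one-out cross-validated Q2. Co-inertia
analysis decomposes the cross-covariance of two omics blocks measured on
the same samples; the RV coefficient summarises their global congruence.

Matrices are samples x features throughout this module. Scaling helpers
record their transform so an analysis is reproducible from its metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage


@dataclass
class ScaledMatrix:
    data: pd.DataFrame
    log2: bool = False
    scaling: str = "none"  # none | uv | pareto | standard


def scale_matrix(
    m: pd.DataFrame, log2: bool = True, scaling: str = "pareto"
) -> ScaledMatrix:
    """Feature-wise transform: optional log2, then centering/scaling.

    ``pareto`` divides the centered values by sqrt(SD) (SD with n-1), ``uv``
    by SD; ``standard`` is the per-feature z-score used for heatmaps;
    ``none`` centers only.
    """
    x = np.log2(m) if log2 else m.astype(float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1).replace(0, 1.0)
    if scaling == "pareto":
        x = (x - mu) / np.sqrt(sd)
    elif scaling in ("uv", "standard"):
        x = (x - mu) / sd
    elif scaling == "none":
        x = x - mu
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return ScaledMatrix(x, log2=log2, scaling=scaling)


def _fix_sign(scores: np.ndarray, loadings: np.ndarray):
    """Deterministic component orientation: largest-|loading| entry positive."""
    for c in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, c]))
        if loadings[i, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return scores, loadings


def pca(m: ScaledMatrix | pd.DataFrame, n_components: Optional[int] = None):
    """Column-centered SVD; returns (scores, loadings, explained fractions)."""
    x = m.data if isinstance(m, ScaledMatrix) else m
    X = x.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    k = rank if n_components is None else min(n_components, rank)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    scores, loadings = _fix_sign(scores, loadings)
    frac = (s[:rank] ** 2) / np.sum(s[:rank] ** 2)
    cols = [f"PC{i + 1}" for i in range(k)]
    return (
        pd.DataFrame(scores, index=x.index, columns=cols),
        pd.DataFrame(loadings, index=x.columns, columns=cols),
        pd.Series(frac[:k], index=cols, name="explained"),
    )


def ward_cluster(
    m: ScaledMatrix | pd.DataFrame, n_clusters: int = 2, standardize: bool = True
):
    """Agglomerative Ward clustering on Euclidean distances.

    Returns the scipy linkage matrix and flat labels at ``n_clusters``.
    """
    x = m.data if isinstance(m, ScaledMatrix) else m
    X = x.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = linkage(X, method="ward", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return Z, pd.Series(labels, index=x.index, name="cluster")


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


@dataclass
class OplsModel:
    n_ortho: int
    scores: np.ndarray  # predictive scores t
    ortho_scores: np.ndarray
    weights: np.ndarray  # predictive weights w
    loadings: np.ndarray  # predictive loadings p
    ortho_weights: np.ndarray
    ortho_loadings: np.ndarray
    coef_q: float  # regression of y on t
    y_mean: float
    r2x: float = np.nan
    r2y: float = np.nan
    q2: float = np.nan
    vip: Optional[pd.Series] = None
    perm_p_r2y: float = np.nan
    perm_p_q2: float = np.nan
    loocv_q2: list = field(default_factory=list)


def _encode_labels(labels) -> np.ndarray:
    uniq = sorted(pd.unique(pd.Series(labels)))
    if len(uniq) != 2:
        raise ValueError("OPLS-DA needs exactly two classes")
    y = np.where(np.asarray(labels) == uniq[0], 1.0, -1.0)
    if min((y == 1).sum(), (y == -1).sum()) < 2:
        raise ValueError("each class needs >= 2 samples")
    return y


def _fit_opls(X: np.ndarray, y: np.ndarray, n_ortho: int):
    """Core NIPALS O-PLS fit on centered X and centered y."""
    Xd = X.copy()
    w_os, p_os, t_os = [], [], []
    for _ in range(n_ortho):
        w = Xd.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        w_os.append(w_o)
        p_os.append(p_o)
        t_os.append(t_o)
    w = Xd.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    q = (y @ t) / (t @ t)
    return {
        "w": w,
        "t": t,
        "p": p,
        "q": q,
        "Wo": np.array(w_os).T if w_os else np.zeros((X.shape[1], 0)),
        "Po": np.array(p_os).T if p_os else np.zeros((X.shape[1], 0)),
        "To": np.array(t_os).T if t_os else np.zeros((X.shape[0], 0)),
    }


def _predict_opls(fit, Xnew: np.ndarray) -> np.ndarray:
    """Predict centered y for new centered rows: strip orthogonal variation first."""
    Xd = Xnew.copy()
    Wo, Po = fit["Wo"], fit["Po"]
    for c in range(Wo.shape[1]):
        t_o = Xd @ Wo[:, c]
        Xd = Xd - np.outer(t_o, Po[:, c])
    return (Xd @ fit["w"]) * fit["q"]


def _loocv_q2(X: np.ndarray, y: np.ndarray, n_ortho: int) -> float:
    n = len(y)
    press, tss = 0.0, 0.0
    for i in range(n):
        idx = np.arange(n) != i
        Xtr, ytr = X[idx], y[idx]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        fit = _fit_opls(Xtr - xm, ytr - ym, n_ortho)
        pred = _predict_opls(fit, (X[i] - xm)[None, :])[0] + ym
        press += (y[i] - pred) ** 2
        tss += (y[i] - ym) ** 2
    return 1.0 - press / tss


def opls_da(
    m: ScaledMatrix | pd.DataFrame,
    labels,
    n_ortho: Optional[int] = None,
    max_ortho: Optional[int] = None,
    q2_floor: float = 0.01,
) -> OplsModel:
    """OPLS-DA with LOOCV-selected orthogonal-component count.

    The orthogonal count grows from 0 while the LOOCV Q2 improves by at
    least ``q2_floor``, capped at min(5, n-2). R2X/R2Y come from the full
    fit, Q2 = 1 - PRESS/TSS from the leave-one-out predictions, and VIP
    scores are computed over the predictive component (mean squared VIP = 1).
    """
    x = m.data if isinstance(m, ScaledMatrix) else m
    X0 = x.to_numpy(dtype=float)
    if X0.shape[1] < 1:
        raise ValueError("need at least one feature")
    y0 = _encode_labels(labels)
    n = len(y0)
    cap = min(5, n - 2) if max_ortho is None else max_ortho
    q2s = []
    if n_ortho is None:
        best_k, best_q2 = 0, -np.inf
        for k in range(cap + 1):
            q2 = _loocv_q2(X0, y0, k)
            q2s.append(q2)
            if q2 > best_q2 + q2_floor:
                best_k, best_q2 = k, q2
            elif k > best_k:
                break
        n_ortho = best_k
        q2_final = q2s[best_k]
    else:
        q2_final = _loocv_q2(X0, y0, n_ortho)
        q2s = [q2_final]
    xm, ym = X0.mean(axis=0), y0.mean()
    Xc, yc = X0 - xm, y0 - ym
    fit = _fit_opls(Xc, yc, n_ortho)
    t, p, q, w = fit["t"], fit["p"], fit["q"], fit["w"]
    ssx = np.sum(Xc**2)
    ssx_expl = np.sum(np.outer(t, p) ** 2)
    for c in range(fit["To"].shape[1]):
        ssx_expl += np.sum(np.outer(fit["To"][:, c], fit["Po"][:, c]) ** 2)
    yhat = t * q
    r2y = 1.0 - np.sum((yc - yhat) ** 2) / np.sum(yc**2)
    nfeat = X0.shape[1]
    vip = np.sqrt(nfeat) * np.abs(w) / np.linalg.norm(w)
    model = OplsModel(
        n_ortho=n_ortho,
        scores=t,
        ortho_scores=fit["To"],
        weights=w,
        loadings=p,
        ortho_weights=fit["Wo"],
        ortho_loadings=fit["Po"],
        coef_q=q,
        y_mean=ym,
        r2x=float(ssx_expl / ssx),
        r2y=float(r2y),
        q2=float(q2_final),
        vip=pd.Series(vip, index=x.columns, name="VIP"),
        loocv_q2=q2s,
    )
    assert np.isclose((model.vip**2).mean(), 1.0)
    return model


def permutation_test(
    statistic,
    m: ScaledMatrix | pd.DataFrame,
    labels,
    n_perm: int = 200,
    seed: int = 0,
) -> float:
    """Label-permutation p-value with the add-one estimator.

    ``statistic`` maps (matrix, labels) to a scalar; p = (1 + #{perm >=
    observed}) / (1 + n_perm), so the attainable floor is 1/(n_perm + 1).
    """
    labels = np.asarray(labels)
    obs = statistic(m, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += statistic(m, rng.permutation(labels)) >= obs
    return (1 + hits) / (1 + n_perm)


def opls_da_with_permutation(
    m: ScaledMatrix | pd.DataFrame, labels, n_perm: int = 200, seed: int = 0
) -> OplsModel:
    model = opls_da(m, labels)

    def stat_r2y(mm, ll):
        return opls_da(mm, ll, n_ortho=model.n_ortho).r2y

    def stat_q2(mm, ll):
        return opls_da(mm, ll, n_ortho=model.n_ortho).q2

    model.perm_p_r2y = permutation_test(stat_r2y, m, labels, n_perm, seed)
    model.perm_p_q2 = permutation_test(stat_q2, m, labels, n_perm, seed + 1)
    return model


# ---------------------------------------------------------------------------
# co-inertia analysis
# ---------------------------------------------------------------------------


@dataclass
class CiaResult:
    rv: float
    axis_fractions: np.ndarray
    x_coords: pd.DataFrame
    y_coords: pd.DataFrame
    perm_p: float = np.nan


def rv_coefficient(X: np.ndarray, Y: np.ndarray) -> float:
    """RV = tr(XX'YY') / sqrt(tr((XX')^2) tr((YY')^2)) on centered blocks."""
    Sx, Sy = X @ X.T, Y @ Y.T
    num = np.trace(Sx @ Sy)
    den = np.sqrt(np.trace(Sx @ Sx) * np.trace(Sy @ Sy))
    return float(num / den) if den > 0 else np.nan


def coinertia(
    x: ScaledMatrix | pd.DataFrame,
    y: ScaledMatrix | pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
    n_axes: int = 2,
) -> CiaResult:
    """Co-inertia of two blocks on identical samples (same order).

    Axes are the SVD of the cross-covariance X'Y of the centered blocks;
    per-axis fractions are squared singular values over their total. The
    permutation p row-permutes one block and recomputes RV.
    """
    xd = x.data if isinstance(x, ScaledMatrix) else x
    yd = y.data if isinstance(y, ScaledMatrix) else y
    if list(xd.index) != list(yd.index):
        raise ValueError("blocks must share samples in identical order")
    X = xd.to_numpy(dtype=float)
    Y = yd.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    U, s, Vt = np.linalg.svd(X.T @ Y, full_matrices=False)
    frac = s**2 / np.sum(s**2)
    k = min(n_axes, len(s))
    U, V = U[:, :k].copy(), Vt[:k].T.copy()
    # orient each axis pair jointly (largest-|x-loading| positive)
    for c in range(k):
        if U[np.argmax(np.abs(U[:, c])), c] < 0:
            U[:, c] *= -1
            V[:, c] *= -1
    xs = X @ U
    ys = Y @ V
    rv = rv_coefficient(X, Y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        hits += rv_coefficient(X, Y[rng.permutation(len(Y))]) >= rv
    perm_p = (1 + hits) / (1 + n_perm)
    cols = [f"Axis{i + 1}" for i in range(k)]
    return CiaResult(
        rv=rv,
        axis_fractions=frac,
        x_coords=pd.DataFrame(xs, index=xd.index, columns=cols),
        y_coords=pd.DataFrame(ys, index=yd.index, columns=cols),
        perm_p=float(perm_p),
    )
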