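"""Four-stage lipidomics quality control with D-ratio filtering and kNN imputation.

A shotgun-lipidomics concentration table (species x samples, nmol/g) is
cleaned in four sequential stages, each operating on what the previous stage
left behind:

1. pool missingness   - drop species missing in more than ``max_pool_missing``
                        (default 35%) of the QC-pool injections;
2. group missingness  - drop species missing in at least ``max_group_missing``
                        (default 50%) of the samples of *every* biological
                        group;
3. pool CV            - drop species whose coefficient of variation over the
                        observed QC-pool values exceeds ``max_cv`` (25%);
4. D-ratio            - drop species whose dispersion ratio
                        sigma_tech / sqrt(sigma_biol^2 + sigma_tech^2)
                        exceeds ``max_d_ratio`` (50%), i.e. species dominated
                        by technical rather than biological variance.

Remaining missing values are imputed with an observation-selective kNN:
the k nearest species (Euclidean distance on jointly observed, per-species
standardized profiles) that are observed in the target sample vote by a
1/distance-weighted mean of their raw values in that sample.

All variances use linear-scale concentrations with n-1 denominators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd

from .design import ROLE_BIOLOGICAL, ROLE_POOL, biological_samples, pool_samples

STAGE_POOL_MISSING = "pool_missing"
STAGE_GROUP_MISSING = "group_missing"
STAGE_CV = "cv"
STAGE_D_RATIO = "d_ratio"
STAGES = (STAGE_POOL_MISSING, STAGE_GROUP_MISSING, STAGE_CV, STAGE_D_RATIO)


@dataclass
class QCParams:
    max_pool_missing: float = 0.35   # strict >
    max_group_missing: float = 0.50  # inclusive >=, in every group
    max_cv: float = 0.25             # strict >
    max_d_ratio: float = 0.50        # strict >
    knn_k: int = 10


@dataclass
class LipidQCReport:
    removed: Dict[str, List[str]] = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0
    n_imputed: int = 0
    table: pd.DataFrame | None = None

    @property
    def counts(self) -> Dict[str, int]:
        return {stage: len(self.removed.get(stage, [])) for stage in STAGES}

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "n_imputed": self.n_imputed,
            "counts": self.counts,
            "removed": {k: list(v) for k, v in self.removed.items()},
        }


def d_ratio(sigma_tech: float, sigma_biol: float) -> float:
    """Dispersion ratio sigma_tech / sqrt(sigma_biol^2 + sigma_tech^2) in [0, 1]."""
    if sigma_tech < 0 or sigma_biol < 0:
        raise ValueError("standard deviations must be >= 0")
    denom = np.sqrt(sigma_biol**2 + sigma_tech**2)
    if denom == 0.0:
        warnings.warn("D-ratio 0/0 encountered; defined as 0", stacklevel=2)
        return 0.0
    return float(sigma_tech / denom)


def _pool_missing_frac(t: pd.DataFrame, pools: list) -> pd.Series:
    if not pools:
        raise ValueError("design has no qc_pool samples")
    return t[pools].isna().mean(axis=1)


def pool_missing_mask(t: pd.DataFrame, design: pd.DataFrame, max_frac: float) -> pd.Series:
    return _pool_missing_frac(t, pool_samples(design)) > max_frac


def filter_pool_missingness(t, design, max_frac: float = 0.35):
    mask = pool_missing_mask(t, design, max_frac)
    return t.loc[~mask], t.index[mask].tolist()


def group_missing_mask(t: pd.DataFrame, design: pd.DataFrame, max_frac: float) -> pd.Series:
    bio = biological_samples(design)
    groups = [g for g in bio["group"].unique() if g != ""]
    if len(groups) < 1:
        raise ValueError("no biological groups in design")
    mask = pd.Series(True, index=t.index)
    for g in groups:
        cols = bio.loc[bio["group"] == g, "sample"].tolist()
        mask &= t[cols].isna().mean(axis=1) >= max_frac
    return mask


def filter_group_missingness(t, design, max_frac: float = 0.50):
    mask = group_missing_mask(t, design, max_frac)
    return t.loc[~mask], t.index[mask].tolist()


def pool_cv(t: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    """CV = sample SD / mean over observed QC-pool values, linear scale."""
    p = t[pool_samples(design)]
    return p.std(axis=1, ddof=1) / p.mean(axis=1)


def cv_mask(t, design, max_cv: float) -> pd.Series:
    return pool_cv(t, design).fillna(0.0) > max_cv


def filter_cv(t, design, max_cv: float = 0.25):
    mask = cv_mask(t, design, max_cv)
    return t.loc[~mask], t.index[mask].tolist()


def species_d_ratio(t: pd.DataFrame, design: pd.DataFrame) -> pd.Series:
    pools = pool_samples(design)
    bio = biological_samples(design)["sample"].tolist()
    s_tech = t[pools].std(axis=1, ddof=1)
    s_biol = t[bio].std(axis=1, ddof=1)
    denom = np.sqrt(s_biol**2 + s_tech**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = s_tech / denom
    return d.fillna(0.0)


def d_ratio_mask(t, design, max_d: float) -> pd.Series:
    return species_d_ratio(t, design) > max_d


def filter_d_ratio(t, design, max_d: float = 0.50):
    mask = d_ratio_mask(t, design, max_d)
    return t.loc[~mask], t.index[mask].tolist()


def knn_impute(t: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Observation-selective kNN imputation.

    Distances are Euclidean on per-species standardized profiles restricted
    to the samples jointly observed with the target species; a neighbour is
    eligible for a given missing cell only if it is observed in that sample.
    Eligible neighbours vote by a 1/distance-weighted mean of their raw
    values; zero-distance neighbours take the cell outright (equal split on
    ties). Observed entries are never touched.
    """
    if not t.isna().any().any():
        return t.copy()
    out = t.copy()
    vals = t.to_numpy(dtype=float)
    mu = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (vals - mu) / sd
    obs = ~np.isnan(vals)
    index = t.index
    for i in np.flatnonzero(~obs.all(axis=1)):
        for j in np.flatnonzero(~obs[i]):
            elig = np.flatnonzero(obs[:, j])
            elig = elig[elig != i]
            if elig.size == 0:
                warnings.warn(
                    f"no eligible neighbour for {index[i]!r}; species-mean fallback",
                    stacklevel=2,
                )
                out.iat[i, j] = float(mu[i, 0])
                continue
            dists = np.empty(elig.size)
            for a, e in enumerate(elig):
                shared = obs[i] & obs[e]
                if not shared.any():
                    dists[a] = np.inf
                    continue
                diff = z[i, shared] - z[e, shared]
                dists[a] = np.sqrt(np.mean(diff**2))
            finite = np.isfinite(dists)
            if not finite.any():
                out.iat[i, j] = float(mu[i, 0])
                continue
            elig, dists = elig[finite], dists[finite]
            order = np.argsort(dists, kind="stable")
            if order.size < k:
                warnings.warn(
                    f"only {order.size} eligible neighbours (<k={k}) for {index[i]!r}",
                    stacklevel=2,
                )
            nearest = order[:k]
            nd, nv = dists[nearest], vals[elig[nearest], j]
            if np.any(nd == 0):
                out.iat[i, j] = float(nv[nd == 0].mean())
            else:
                w = 1.0 / nd
                out.iat[i, j] = float(np.sum(w * nv) / np.sum(w))
    return out


def run_qc(t: pd.DataFrame, design: pd.DataFrame, params: QCParams | None = None) -> LipidQCReport:
    """Apply the four filters sequentially, then kNN-impute the survivors.

    The cleaned table retains the biological and QC-pool columns; blanks are
    carried through the raw table for bookkeeping only and are dropped here.
    """
    params = params or QCParams()
    report = LipidQCReport(n_in=len(t))
    cur = t
    cur, report.removed[STAGE_POOL_MISSING] = filter_pool_missingness(
        cur, design, params.max_pool_missing
    )
    cur, report.removed[STAGE_GROUP_MISSING] = filter_group_missingness(
        cur, design, params.max_group_missing
    )
    cur, report.removed[STAGE_CV] = filter_cv(cur, design, params.max_cv)
    cur, report.removed[STAGE_D_RATIO] = filter_d_ratio(cur, design, params.max_d_ratio)
    keep = design.loc[design["role"].isin([ROLE_BIOLOGICAL, ROLE_POOL]), "sample"]
    cur = cur[[c for c in cur.columns if c in set(keep)]]
    report.n_imputed = int(cur.isna().to_numpy().sum())
    report.table = knn_impute(cur, k=params.knn_k)
    report.n_out = len(cur)
    assert report.n_in == report.n_out + sum(report.counts.values())
    return report
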