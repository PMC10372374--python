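"""Post-quantification processing of a precursor-level DIA report.

The pipeline order is fixed: q-value/flag filtering -> charge-state
summation to peptides -> MaxLFQ protein quantification -> detection-rate
filter -> iterative imputation. Input is a long-format table with one row
per precursor x run, carrying global and run-specific precursor q-values,
the protein-group global q-value, contaminant/proteotypic flags and the
measured intensity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer
from sklearn.linear_model import Ridge

REQUIRED_COLUMNS = (
    "run",
    "precursor_id",
    "peptide",
    "charge",
    "protein",
    "proteotypic",
    "contaminant",
    "q_value",
    "run_q_value",
    "pg_q_value",
    "intensity",
)

#: column-name dialects for common DIA report layouts
DIANN_DIALECT: Dict[str, str] = {
    "Run": "run",
    "Precursor.Id": "precursor_id",
    "Modified.Sequence": "peptide",
    "Precursor.Charge": "charge",
    "Protein.Group": "protein",
    "Proteotypic": "proteotypic",
    "Q.Value": "run_q_value",
    "Global.Q.Value": "q_value",
    "Global.PG.Q.Value": "pg_q_value",
    "Precursor.Quantity": "intensity",
    "Quantity.Quality": "quality",
}


def read_precursor_report(path, column_map: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    if column_map:
        t = t.rename(columns=column_map)
    missing = set(REQUIRED_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"precursor report missing columns: {sorted(missing)}")
    return t


@dataclass
class FilterLog:
    removed: Dict[str, int] = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0


def filter_precursors(
    t: pd.DataFrame,
    q_threshold: float = 0.01,
    quality_min: Optional[float] = None,
) -> tuple[pd.DataFrame, FilterLog]:
    """FDR filtering of precursor rows.

    A row survives iff its precursor global q, run-specific q and
    protein-group global q are all <= ``q_threshold``, it is proteotypic and
    not a contaminant, and (when a quality column is present and a floor is
    configured) its signal-quality score is >= ``quality_min``. Removal
    counts per criterion are logged; a row failing several criteria is
    counted under each.
    """
    missing = set(REQUIRED_COLUMNS) - set(t.columns)
    if missing:
        raise ValueError(f"precursor table missing columns: {sorted(missing)}")
    log = FilterLog(n_in=len(t))
    crit = {
        "global_q": t["q_value"] <= q_threshold,
        "run_q": t["run_q_value"] <= q_threshold,
        "pg_q": t["pg_q_value"] <= q_threshold,
        "contaminant": ~t["contaminant"].astype(bool),
        "proteotypic": t["proteotypic"].astype(bool),
    }
    if quality_min is not None and "quality" in t.columns:
        crit["quality"] = t["quality"] >= quality_min
    keep = pd.Series(True, index=t.index)
    for name, ok in crit.items():
        log.removed[name] = int((~ok).sum())
        keep &= ok
    out = t.loc[keep]
    log.n_out = len(out)
    return out, log


def aggregate_peptides(t: pd.DataFrame) -> pd.DataFrame:
    """Sum charge states into a (peptide, protein) x run intensity matrix.

    Missing measurements are absent, not zero: the sum runs over observed
    charges only and a peptide unobserved in a run stays missing there.
    """
    m = t.pivot_table(
        index=["peptide", "protein"],
        columns="run",
        values="intensity",
        aggfunc=lambda x: x.sum(min_count=1),
    )
    # a run observed nowhere for a peptide stays a missing column, not absent
    return m.reindex(columns=sorted(t["run"].unique()))


def _maxlfq_profile(pep: np.ndarray, min_pairs: int) -> np.ndarray:
    """Per-protein MaxLFQ: median pairwise log-ratios reconciled by least squares.

    ``pep`` is a peptides x samples log2 matrix with NaN for missing. The
    sample log2 abundances x solve min sum_(j,k) (x_k - x_j - r_jk)^2 over
    valid pairs (>= min_pairs shared peptides), anchored so that the mean
    abundance over each connected set of samples equals the mean log2
    peptide sum of those samples. Samples in no valid pair stay missing.
    """
    n = pep.shape[1]
    obs = ~np.isnan(pep)
    x = np.full(n, np.nan)
    pairs = []
    for j in range(n):
        for k in range(j + 1, n):
            shared = obs[:, j] & obs[:, k]
            if shared.sum() >= max(min_pairs, 1):
                r = np.median(pep[shared, k] - pep[shared, j])
                pairs.append((j, k, r))
    if not pairs:
        return x
    # connected components of the pair graph; solve each separately
    adj = {j: set() for j in range(n)}
    for j, k, _ in pairs:
        adj[j].add(k)
        adj[k].add(j)
    seen = set()
    log_sums = np.full(n, np.nan)
    for j in range(n):
        if obs[:, j].any():
            log_sums[j] = np.log2(np.nansum(2.0 ** pep[obs[:, j], j]))
    for start in range(n):
        if start in seen or not adj[start]:
            continue
        comp = []
        stack = [start]
        while stack:
            v = stack.pop()
            if v in seen:
                continue
            seen.add(v)
            comp.append(v)
            stack.extend(adj[v] - seen)
        comp = sorted(comp)
        pos = {s: i for i, s in enumerate(comp)}
        rows, rhs = [], []
        for j, k, r in pairs:
            if j in pos:
                row = np.zeros(len(comp))
                row[pos[k]] = 1.0
                row[pos[j]] = -1.0
                rows.append(row)
                rhs.append(r)
        A = np.array(rows)
        sol, *_ = np.linalg.lstsq(A, np.array(rhs), rcond=None)
        sol = sol - sol.mean() + np.nanmean(log_sums[comp])
        for s in comp:
            x[s] = sol[pos[s]]
    return x


def maxlfq(peptides: pd.DataFrame, min_pairs: int = 1) -> tuple[pd.DataFrame, pd.DataFrame]:
    """MaxLFQ protein quantification from a (peptide, protein) x run matrix.

    Returns the linear-scale protein x sample matrix and a provenance table
    (peptides per protein, detection rate).
    """
    if not isinstance(peptides.index, pd.MultiIndex) or peptides.index.names != [
        "peptide",
        "protein",
    ]:
        raise ValueError("expected a (peptide, protein)-indexed matrix")
    samples = list(peptides.columns)
    profiles, prov = {}, []
    for protein, block in peptides.groupby(level="protein", sort=True):
        pep = np.log2(block.to_numpy(dtype=float))
        x = _maxlfq_profile(pep, min_pairs)
        if np.isnan(x).all() and (~np.isnan(pep)).any():
            # observations exist but no sample pair shares a peptide
            warnings.warn(
                f"protein {protein!r}: no valid sample pair; profile missing",
                stacklevel=2,
            )
        profiles[protein] = 2.0**x
        det = float(np.mean(~np.isnan(x)))
        prov.append((protein, block.shape[0], det))
    mat = pd.DataFrame(profiles, index=samples).T
    mat.index.name = "protein"
    provenance = pd.DataFrame(
        prov, columns=["protein", "n_peptides", "detection_rate"]
    ).set_index("protein")
    return mat, provenance


def detection_filter(m: pd.DataFrame, min_rate: float = 0.60) -> pd.DataFrame:
    """Keep proteins observed in at least ``min_rate`` of all samples (inclusive)."""
    rate = m.notna().mean(axis=1)
    return m.loc[rate >= min_rate]


def impute_iterative(
    m: pd.DataFrame,
    seed: int = 0,
    max_iter: int = 10,
    tol: float = 1e-4,
) -> pd.DataFrame:
    """Fill missing protein intensities by iterative regression imputation.

    Each protein with missing values is regressed (ridge, log2 scale) on the
    others across samples and the cycle repeats until the imputed values
    stabilise. Observed values are never altered; the result is linear-scale
    and deterministic for a fixed seed.
    """
    if (m.notna().sum(axis=1) == 0).any():
        empty = m.index[m.notna().sum(axis=1) == 0].tolist()
        raise ValueError(f"all-missing proteins cannot be imputed: {empty[:5]}")
    if not m.isna().any().any():
        return m.copy()
    log = np.log2(m.to_numpy(dtype=float)).T  # samples x proteins
    imputer = IterativeImputer(
        estimator=Ridge(alpha=1e-6),
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
        sample_posterior=False,
        keep_empty_features=True,
    )
    filled = imputer.fit_transform(log).T
    out = pd.DataFrame(2.0**filled, index=m.index, columns=m.columns)
    return m.where(m.notna(), out)


def prepare_proteins(
    report: pd.DataFrame,
    q_threshold: float = 0.01,
    min_detection: float = 0.60,
    seed: int = 0,
    quality_min: Optional[float] = None,
) -> tuple[pd.DataFrame, dict]:
    """Full post-processing chain: filter -> aggregate -> MaxLFQ -> detect -> impute."""
    filtered, log = filter_precursors(report, q_threshold, quality_min)
    peptides = aggregate_peptides(filtered)
    mat, prov = maxlfq(peptides)
    mat = detection_filter(mat, min_detection)
    mat = impute_iterative(mat, seed=seed)
    info = {
        "filter": {"n_in": log.n_in, "n_out": log.n_out, "removed": log.removed},
        "n_peptides": int(len(peptides)),
        "n_proteins_quantified": int(len(prov)),
        "n_proteins_kept": int(len(mat)),
    }
    return mat, info
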