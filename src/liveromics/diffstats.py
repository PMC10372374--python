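"""Per-feature two-way ANOVA with pooled BH correction, fold changes,
Tukey HSD follow-up, clinical insulin-sensitivity indices and t-tests.

The differential-abundance model is a 2 (group: PHG/PNG) x 2 (sex: F/M)
linear model fitted to log2 abundances feature by feature. Because the
design is unbalanced, main-effect sums of squares default to Type II (each
main effect adjusted for the other, interaction last); Type I and III are
available. The raw p-values of all three effects across all features of one
omics dataset enter a single Benjamini-Hochberg step-up ("pooled BH").
"""

from __future__ import annotations

import warnings
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EFFECTS = ("group", "sex", "interaction")


def _design_columns(design: pd.DataFrame, samples: Sequence[str]) -> Tuple[np.ndarray, np.ndarray]:
    d = design.set_index("sample").loc[list(samples)]
    groups = sorted(d["group"].unique())
    sexes = sorted(d["sex"].unique())
    if len(groups) != 2 or len(sexes) != 2:
        raise ValueError("two-way ANOVA needs exactly 2 groups and 2 sexes")
    # effect (+1/-1) coding; Type I/II are coding-invariant, Type III needs it
    a = np.where(d["group"] == groups[0], 1.0, -1.0)
    b = np.where(d["sex"] == sexes[0], 1.0, -1.0)
    return a, b


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y (n x p) on design X (n x k), per column."""
    Q, _ = np.linalg.qr(X)
    R = Y - Q @ (Q.T @ Y)
    return np.einsum("ij,ij->j", R, R)


def two_way_anova(
    m: pd.DataFrame,
    design: pd.DataFrame,
    ss_type: str = "II",
) -> pd.DataFrame:
    """F-tests for group, sex and group x sex per feature.

    ``m`` is a feature x sample matrix of log2 abundances (no missing
    values). Returns a DataFrame with columns p_group, p_sex, p_interaction.
    Constant features get p = 1 for every effect with a warning.
    """
    if m.isna().any().any():
        raise ValueError("ANOVA input must not contain missing values")
    a, b = _design_columns(design, m.columns)
    n = len(a)
    Y = m.to_numpy(dtype=float).T  # samples x features
    one = np.ones(n)
    ab = a * b
    X_full = np.column_stack([one, a, b, ab])
    X_main = np.column_stack([one, a, b])
    X_a = np.column_stack([one, a])
    X_b = np.column_stack([one, b])
    # estimability: every cell must be populated for the interaction
    cells = {(x, y) for x, y in zip(a, b)}
    if len(cells) < 4:
        raise ValueError("empty design cell; interaction inestimable")
    df_res = n - 4
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    rss_full = _rss(X_full, Y)
    rss_main = _rss(X_main, Y)
    if ss_type == "II":
        ss_a = _rss(X_b, Y) - rss_main
        ss_b = _rss(X_a, Y) - rss_main
    elif ss_type == "I":
        rss_0 = _rss(one[:, None], Y)
        ss_a = rss_0 - _rss(X_a, Y)
        ss_b = _rss(X_a, Y) - rss_main
    elif ss_type == "III":
        ss_a = _rss(np.column_stack([one, b, ab]), Y) - rss_full
        ss_b = _rss(np.column_stack([one, a, ab]), Y) - rss_full
    else:
        raise ValueError("ss_type must be 'I', 'II' or 'III'")
    ss_ab = rss_main - rss_full
    mse = rss_full / df_res
    out = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for name, ss in (("group", ss_a), ("sex", ss_b), ("interaction", ss_ab)):
            F = (ss / 1.0) / mse
            out[f"p_{name}"] = stats.f.sf(F, 1, df_res)
    res = pd.DataFrame(out, index=m.index)
    const = Y.var(axis=0) == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s): p set to 1", stacklevel=2
        )
        res.loc[const] = 1.0
    return res.clip(upper=1.0).fillna(1.0)


def pool_bh(pvals: pd.DataFrame) -> pd.DataFrame:
    """One BH step-up over all effects x features of a single omics dataset.

    Missing p-values are excluded from the number of hypotheses and stay
    missing in the output.
    """
    flat = pvals.to_numpy(dtype=float).ravel()
    ok = ~np.isnan(flat)
    adj = np.full_like(flat, np.nan)
    if ok.sum() > 0:
        adj[ok] = multipletests(flat[ok], method="fdr_bh")[1]
    out = pd.DataFrame(
        adj.reshape(pvals.shape), index=pvals.index, columns=pvals.columns
    )
    return out.rename(columns=lambda c: c.replace("p_", "q_"))


def tukey_hsd(values: pd.Series, design: pd.DataFrame) -> pd.DataFrame:
    """All pairwise group x sex cell comparisons, studentized-range adjusted.

    Unbalanced cells use the Tukey-Kramer form. Run this only for features
    whose interaction effect is significant.
    """
    d = design.set_index("sample").loc[values.index]
    cells = sorted({(g, s) for g, s in zip(d["group"], d["sex"])})
    arrays = [
        values[(d["group"] == g) & (d["sex"] == s)].to_numpy() for g, s in cells
    ]
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            rows.append(
                (
                    "_".join(cells[i]),
                    "_".join(cells[j]),
                    float(np.mean(arrays[i]) - np.mean(arrays[j])),
                    float(res.pvalue[i, j]),
                )
            )
    return pd.DataFrame(rows, columns=["cell_a", "cell_b", "mean_diff", "p_adj"])


def fold_change(
    m: pd.DataFrame,
    design: pd.DataFrame,
    numerator: str = "PHG",
    denominator: str = "PNG",
    on_log_means: bool = False,
) -> pd.Series:
    """log2 fold change between group means (positive = higher in numerator).

    Default is the ratio of linear-scale group means computed after
    imputation; ``on_log_means`` switches to the difference of log2 means.
    """
    d = design.set_index("sample").loc[m.columns]
    num_cols = m.columns[d["group"] == numerator]
    den_cols = m.columns[d["group"] == denominator]
    if len(num_cols) == 0 or len(den_cols) == 0:
        raise ValueError("both groups must be present in the matrix")
    if on_log_means:
        fc = np.log2(m[num_cols]).mean(axis=1) - np.log2(m[den_cols]).mean(axis=1)
    else:
        fc = np.log2(m[num_cols].mean(axis=1) / m[den_cols].mean(axis=1))
    return fc.rename("l2fc")


def call_significance(
    stats_table: pd.DataFrame,
    p_max: float = 0.05,
    min_fold: float = 1.5,
) -> Tuple[pd.DataFrame, Dict]:
    """Flag features with adjusted p <= p_max and linear fold >= min_fold.

    ``stats_table`` needs q_group/q_sex/q_interaction plus l2fc (group fold,
    PHG/PNG) and optionally l2fc_sex. Bounds are inclusive. The group and
    sex flags combine the p and fold criteria; the interaction flag uses the
    adjusted p only (a 2x2 interaction has no single two-group fold).
    """
    min_l2 = np.log2(min_fold)
    out = stats_table.copy()
    out["sig_group"] = (out["q_group"] <= p_max) & (out["l2fc"].abs() >= min_l2)
    if "l2fc_sex" in out.columns:
        out["sig_sex"] = (out["q_sex"] <= p_max) & (out["l2fc_sex"].abs() >= min_l2)
    else:
        out["sig_sex"] = out["q_sex"] <= p_max
    out["sig_interaction"] = out["q_interaction"] <= p_max
    summary = {
        "group": {
            "total": int(out["sig_group"].sum()),
            "up": int((out["sig_group"] & (out["l2fc"] > 0)).sum()),
            "down": int((out["sig_group"] & (out["l2fc"] < 0)).sum()),
        },
        "sex": {"total": int(out["sig_sex"].sum())},
        "interaction": {"total": int(out["sig_interaction"].sum())},
    }
    return out, summary


def differential_abundance(
    m_linear: pd.DataFrame,
    design: pd.DataFrame,
    ss_type: str = "II",
    p_max: float = 0.05,
    min_fold: float = 1.5,
) -> Tuple[pd.DataFrame, Dict]:
    """ANOVA on log2 values, pooled BH, fold changes and significance calls."""
    log2m = np.log2(m_linear)
    p = two_way_anova(log2m, design, ss_type=ss_type)
    q = pool_bh(p)
    tbl = pd.concat([p, q], axis=1)
    tbl["l2fc"] = fold_change(m_linear, design)
    d = design.set_index("sample").loc[m_linear.columns]
    f_cols = m_linear.columns[d["sex"] == "F"]
    m_cols = m_linear.columns[d["sex"] == "M"]
    if len(f_cols) and len(m_cols):
        tbl["l2fc_sex"] = np.log2(
            m_linear[f_cols].mean(axis=1) / m_linear[m_cols].mean(axis=1)
        )
    return call_significance(tbl, p_max=p_max, min_fold=min_fold)


# ---------------------------------------------------------------------------
# clinical indices and simple group tests
# ---------------------------------------------------------------------------


def homa_ir(insulin, glucose):
    """HOMA-IR = fasting insulin (uU/mL) x fasting glucose (mg/dL) / 405."""
    insulin = np.asarray(insulin, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    if np.any(insulin <= 0) or np.any(glucose <= 0):
        raise ValueError("insulin and glucose must be positive")
    return insulin * glucose / 405.0


QUICKI_CUTOFF = 0.45  # values below indicate decreased insulin sensitivity


def quicki(insulin, glucose):
    """QUICKI = 1 / [log10(insulin (mU/L)) + log10(glucose (mg/dL))]."""
    insulin = np.asarray(insulin, dtype=float)
    glucose = np.asarray(glucose, dtype=float)
    if np.any(insulin <= 0) or np.any(glucose <= 0):
        raise ValueError("insulin and glucose must be positive")
    s = np.log10(insulin) + np.log10(glucose)
    if np.any(s <= 0):
        raise ValueError("QUICKI undefined: log10 insulin + log10 glucose <= 0")
    return 1.0 / s


def clinical_indices(clinical: pd.DataFrame) -> pd.DataFrame:
    out = clinical.copy()
    out["homa_ir"] = homa_ir(out["insulin"], out["glucose"])
    out["quicki"] = quicki(out["insulin"], out["glucose"])
    out["low_insulin_sensitivity"] = out["quicki"] < QUICKI_CUTOFF
    return out


def group_t_test(values: Sequence[float], labels: Sequence) -> float:
    """Two-tailed Student's t-test between the two label groups."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two groups required")
    a, b = values[labels == uniq[0]], values[labels == uniq[1]]
    t = stats.ttest_ind(a, b, equal_var=True)
    return float(t.pvalue)
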