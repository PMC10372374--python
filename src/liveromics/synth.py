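"""Synthetic data with known planted structure.

Generators for every input the analysis stages consume: log-normal omics
abundance matrices with planted group/sex/interaction effects on a 2x2
unbalanced design, raw shotgun-lipidomics tables with planted stage-specific
QC violations, scale-free protein-interaction graphs with planted dense
modules, gene-disease catalogues overlapping those modules, and clinical
tables (insulin, glucose). Each generator returns its data together with a
truth ledger recording exactly which features/nodes/species carry which
planted signal, so recovery can be scored.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from . import lipidqc
from .design import ROLE_BIOLOGICAL, StudyDesign

TRUTH_NONE = "none"


@dataclass
class EffectSpec:
    """Planted-effect description for an omics abundance matrix.

    Intensities are log-normal: log2 values are Normal(baseline + effects,
    sigma_bio). Affected features receive a log2 shift whose linear fold is
    drawn uniformly from ``fold_change_range`` with a random sign. Group
    effects shift PHG (first group), sex effects shift females, interaction
    effects shift the (first group, F) cell only.
    """

    n_features: int = 1000
    frac_group_affected: float = 0.05
    frac_sex_affected: float = 0.005
    frac_interaction_affected: float = 0.005
    fold_change_range: Tuple[float, float] = (1.5, 5.3)
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    sigma_bio: float = 0.5
    missing_rate: float = 0.0

    def validate(self) -> None:
        fracs = (
            self.frac_group_affected,
            self.frac_sex_affected,
            self.frac_interaction_affected,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("affected fractions must lie in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("sum of affected fractions exceeds 1")
        if self.fold_change_range[0] <= 1:
            raise ValueError("fold_change_range lower bound must be > 1")
        if self.fold_change_range[1] < self.fold_change_range[0]:
            raise ValueError("fold_change_range must be increasing")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.n_features < 1 or self.sigma_bio < 0:
            raise ValueError("need n_features >= 1 and sigma_bio >= 0")


def gen_omics_matrix(
    design: StudyDesign,
    spec: EffectSpec,
    seed: int,
    feature_names: Optional[Sequence[str]] = None,
    group_features: Optional[Sequence[str]] = None,
):
    """Feature x sample linear-intensity matrix plus its truth ledger.

    ``group_features`` optionally forces specific features to be among the
    group-affected set (used to align omics effects with planted network
    modules). Returns ``(matrix, truth)`` where truth has one row per feature
    with its effect label and true log2 fold change.
    """
    spec.validate()
    design.require_testable()
    rng = np.random.default_rng(seed)
    n = spec.n_features
    if feature_names is None:
        feature_names = [f"F{i + 1:05d}" for i in range(n)]
    feature_names = list(feature_names)
    if len(feature_names) != n:
        raise ValueError("feature_names length must equal n_features")

    n_g = int(round(spec.frac_group_affected * n))
    n_s = int(round(spec.frac_sex_affected * n))
    n_i = int(round(spec.frac_interaction_affected * n))
    forced = [f for f in (group_features or [])]
    unknown = set(forced) - set(feature_names)
    if unknown:
        raise ValueError(f"group_features not in feature set: {sorted(unknown)[:5]}")
    if len(forced) > n_g:
        n_g = len(forced)
    pool = [f for f in feature_names if f not in set(forced)]
    perm = rng.permutation(len(pool))
    need_g = n_g - len(forced)
    group_set = set(forced) | {pool[i] for i in perm[:need_g]}
    sex_set = {pool[i] for i in perm[need_g : need_g + n_s]}
    inter_set = {pool[i] for i in perm[need_g + n_s : need_g + n_s + n_i]}

    def draw_l2fc() -> float:
        fold = rng.uniform(*spec.fold_change_range)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return sign * np.log2(fold)

    effects, l2fc = [], []
    for f in feature_names:
        if f in group_set:
            effects.append("group")
            l2fc.append(draw_l2fc())
        elif f in sex_set:
            effects.append("sex")
            l2fc.append(draw_l2fc())
        elif f in inter_set:
            effects.append("interaction")
            l2fc.append(draw_l2fc())
        else:
            effects.append(TRUTH_NONE)
            l2fc.append(0.0)
    truth = pd.DataFrame(
        {"feature": feature_names, "effect": effects, "true_l2fc": l2fc}
    ).set_index("feature")

    samples = design.sample_table()
    bio = samples[samples["role"] == ROLE_BIOLOGICAL]
    ref_group, alt_sex = design.groups[0], design.sexes[0]  # PHG shifted, F shifted
    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, size=n)
    log2m = np.empty((n, len(bio)))
    for j, (_, row) in enumerate(bio.iterrows()):
        shift = np.zeros(n)
        is_phg = row["group"] == ref_group
        is_f = row["sex"] == alt_sex
        fc = truth["true_l2fc"].to_numpy()
        eff = truth["effect"].to_numpy()
        if is_phg:
            shift += np.where(eff == "group", fc, 0.0)
        if is_f:
            shift += np.where(eff == "sex", fc, 0.0)
        if is_phg and is_f:
            shift += np.where(eff == "interaction", fc, 0.0)
        log2m[:, j] = baseline + shift + rng.normal(0, spec.sigma_bio, size=n)

    matrix = pd.DataFrame(2.0**log2m, index=feature_names, columns=bio["sample"].tolist())
    matrix.index.name = "feature"
    if spec.missing_rate > 0:
        # left-censored dropout: probability decays sigmoidally above the
        # 20th-percentile intensity, approximating MNAR omics missingness
        t = np.quantile(log2m, 0.20)
        s = max(np.std(log2m), 1e-9) * 0.5
        p = 2.0 * spec.missing_rate / (1.0 + np.exp((log2m - t) / s))
        drop = rng.random(log2m.shape) < np.minimum(p, 1.0)
        matrix = matrix.mask(drop)
    return matrix, truth


# ---------------------------------------------------------------------------
# raw lipidomics table with planted QC violations
# ---------------------------------------------------------------------------

DEFAULT_PLANTED_COUNTS = (136, 7, 22, 43)


class GenerationError(RuntimeError):
    pass


def _classify_species(values: pd.Series, design: pd.DataFrame, params: lipidqc.QCParams):
    """First QC stage the species fails, evaluated in pipeline order, or None."""
    t = values.to_frame().T
    if lipidqc.pool_missing_mask(t, design, params.max_pool_missing).iloc[0]:
        return lipidqc.STAGE_POOL_MISSING
    if lipidqc.group_missing_mask(t, design, params.max_group_missing).iloc[0]:
        return lipidqc.STAGE_GROUP_MISSING
    if lipidqc.cv_mask(t, design, params.max_cv).iloc[0]:
        return lipidqc.STAGE_CV
    if lipidqc.d_ratio_mask(t, design, params.max_d_ratio).iloc[0]:
        return lipidqc.STAGE_D_RATIO
    return None


def gen_lipid_raw(
    design: StudyDesign,
    n_species: int = 1204,
    planted_counts: Tuple[int, int, int, int] = DEFAULT_PLANTED_COUNTS,
    seed: int = 0,
    missing_rate: float = 0.02,
    max_retries: int = 1000,
    params: lipidqc.QCParams | None = None,
):
    """Raw species x sample concentration table with planted QC failures.

    ``planted_counts`` gives, in pipeline order, the number of species that
    must be removed at the pool-missingness, group-missingness, CV and
    D-ratio stages. Every planted species is verified post hoc (with bounded
    resampling) to fail exactly its stage on the realized finite sample while
    passing all earlier stages; all other species pass every stage.
    """
    if sum(planted_counts) > n_species:
        raise ValueError("sum of planted_counts exceeds n_species")
    if design.n_pool < 2:
        raise ValueError("need >= 2 QC-pool samples")
    params = params or lipidqc.QCParams()
    rng = np.random.default_rng(seed)
    dtab = design.sample_table()
    pools = dtab.loc[dtab["role"] == "qc_pool", "sample"].tolist()
    blanks = dtab.loc[dtab["role"] == "blank", "sample"].tolist()
    bio = dtab[dtab["role"] == ROLE_BIOLOGICAL]
    bio_by_group = {
        g: bio.loc[bio["group"] == g, "sample"].tolist() for g in design.groups
    }
    columns = bio["sample"].tolist() + pools + blanks

    stage_of: list = []
    for stage, count in zip(lipidqc.STAGES, planted_counts):
        stage_of += [stage] * count
    stage_of += [None] * (n_species - len(stage_of))
    order = rng.permutation(n_species)
    names = [f"L{i + 1:04d}" for i in range(n_species)]
    assignment = {names[i]: stage_of[j] for i, j in enumerate(order)}

    def draw_species(target):
        mu = float(np.exp(rng.normal(2.0, 1.0)))
        row = pd.Series(index=columns, dtype=float)
        # blanks: near-zero carryover, half missing
        for b in blanks:
            row[b] = np.nan if rng.random() < 0.5 else abs(rng.normal(0, 0.01 * mu))
        pool_cv_frac = {
            None: 0.05,
            lipidqc.STAGE_POOL_MISSING: 0.05,
            lipidqc.STAGE_GROUP_MISSING: 0.05,
            lipidqc.STAGE_CV: 0.40,
            lipidqc.STAGE_D_RATIO: 0.20,
        }[target]
        bio_cv_frac = 0.10 if target == lipidqc.STAGE_D_RATIO else 0.30
        pv = np.clip(rng.normal(mu, pool_cv_frac * mu, len(pools)), 1e-3 * mu, None)
        row[pools] = pv
        if target == lipidqc.STAGE_POOL_MISSING:
            n_miss = int(np.floor(params.max_pool_missing * len(pools))) + 1
            n_miss = min(max(n_miss, 2), len(pools))
            row[rng.choice(pools, n_miss, replace=False)] = np.nan
        for g, cols in bio_by_group.items():
            bv = np.clip(rng.normal(mu, bio_cv_frac * mu, len(cols)), 1e-3 * mu, None)
            row[cols] = bv
            if target == lipidqc.STAGE_GROUP_MISSING:
                n_miss = int(np.ceil(params.max_group_missing * len(cols)))
                row[rng.choice(cols, n_miss, replace=False)] = np.nan
            elif missing_rate > 0:
                drop = rng.random(len(cols)) < missing_rate
                # never let incidental missingness approach the group rule
                if drop.sum() < params.max_group_missing * len(cols) - 1:
                    row[np.array(cols)[drop]] = np.nan
        return row

    rows = {}
    for name in names:
        target = assignment[name]
        for _ in range(max_retries):
            row = draw_species(target)
            if _classify_species(row[bio["sample"].tolist() + pools], dtab, params) == target:
                rows[name] = row
                break
        else:
            raise GenerationError(
                f"retry budget exhausted planting stage {target!r} for {name}"
            )
    table = pd.DataFrame(rows).T
    table = table.loc[names, columns]
    table.index.name = "species"
    truth = pd.DataFrame(
        {
            "species": names,
            "planted_stage": [
                assignment[n] if assignment[n] is not None else TRUTH_NONE
                for n in names
            ],
        }
    ).set_index("species")
    return table, truth


# ---------------------------------------------------------------------------
# protein-protein interaction graph with planted modules
# ---------------------------------------------------------------------------


def gen_ppi(
    n_nodes: int = 2000,
    attachment_parameter: int = 3,
    planted_modules: Sequence[Tuple[int, float]] = ((10, 0.9),),
    seed: int = 0,
):
    """Scale-free (preferential-attachment) graph with planted dense modules.

    Module-internal edges are added with the given probability and carry
    combined scores > 0.7; background edges carry scores uniform in [0, 1].
    Returns ``(graph, truth)`` with truth mapping node -> module index (-1
    for background).
    """
    if any(size > n_nodes for size, _ in planted_modules):
        raise ValueError("module size exceeds n_nodes")
    g0 = nx.barabasi_albert_graph(n_nodes, attachment_parameter, seed=seed)
    names = {i: f"G{i + 1:05d}" for i in range(n_nodes)}
    g = nx.relabel_nodes(g0, names)
    rng = np.random.default_rng(seed)
    module_of: Dict[str, int] = {n: -1 for n in g.nodes}
    available = sorted(g.nodes)
    for mi, (size, p_in) in enumerate(planted_modules):
        members = rng.choice(available, size=size, replace=False).tolist()
        available = [n for n in available if n not in set(members)]
        for i in range(size):
            for j in range(i + 1, size):
                if rng.random() < p_in:
                    g.add_edge(members[i], members[j])
        for n in members:
            module_of[n] = mi
    for u, v in sorted(g.edges):
        in_module = module_of[u] >= 0 and module_of[u] == module_of[v]
        score = rng.uniform(0.701, 1.0) if in_module else rng.uniform(0.0, 1.0)
        g.edges[u, v]["combined_score"] = float(score)
    truth = pd.DataFrame(
        {"node": sorted(g.nodes), "module": [module_of[n] for n in sorted(g.nodes)]}
    ).set_index("node")
    return g, truth


def ppi_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = [
        (u, v, g.edges[u, v].get("combined_score", 1.0)) for u, v in sorted(g.edges)
    ]
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])


def gen_disease_catalog(
    n_diseases: int,
    gene_pool: Sequence[str],
    overlap_spec: Optional[Mapping[int, Tuple[Sequence[str], int]]] = None,
    seed: int = 0,
    size_range: Tuple[int, int] = (5, 20),
    low_score_frac: float = 0.1,
):
    """Gene-disease table (disease_id, gene, gda_score) with planned overlaps.

    ``overlap_spec`` maps a disease index to ``(module_genes, n_shared)``:
    that disease receives exactly ``n_shared`` genes from the module, the
    rest drawn from outside it. Shared and regular genes score > 0.3; a
    ``low_score_frac`` fraction of extra rows scores below the 0.3 screening
    threshold to exercise the filter.
    """
    overlap_spec = dict(overlap_spec or {})
    rng = np.random.default_rng(seed)
    gene_pool = sorted(gene_pool)
    rows = []
    truth_rows = []
    for d in range(n_diseases):
        did = f"D{d + 1:03d}"
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        if d in overlap_spec:
            module_genes, n_shared = overlap_spec[d]
            module_genes = sorted(module_genes)
            if n_shared > len(module_genes):
                raise ValueError("n_shared exceeds module size")
            size = max(size, n_shared)
            shared = rng.choice(module_genes, n_shared, replace=False).tolist()
            outside = [x for x in gene_pool if x not in set(module_genes)]
            rest = rng.choice(outside, size - n_shared, replace=False).tolist()
            genes = shared + rest
        else:
            genes = rng.choice(gene_pool, size, replace=False).tolist()
        for gname in genes:
            rows.append((did, gname, float(rng.uniform(0.31, 1.0))))
        if low_score_frac > 0 and rng.random() < low_score_frac:
            extra = rng.choice(gene_pool)
            rows.append((did, str(extra), float(rng.uniform(0.01, 0.30))))
        truth_rows.append((did, ";".join(sorted(genes))))
    catalog = pd.DataFrame(rows, columns=["disease_id", "gene", "gda_score"])
    truth = pd.DataFrame(truth_rows, columns=["disease_id", "genes"]).set_index(
        "disease_id"
    )
    return catalog, truth


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

# emulates the reported insulin-resistance contrast: PHG piglets markedly
# insulin-resistant (males more than females), PNG near-zero HOMA-IR
DEFAULT_CLINICAL = {
    ("PHG", "M"): {"insulin": (5.0, 2.0), "glucose": (100.0, 15.0)},
    ("PHG", "F"): {"insulin": (2.6, 1.2), "glucose": (100.0, 15.0)},
    ("PNG", "M"): {"insulin": (0.35, 0.25), "glucose": (95.0, 12.0)},
    ("PNG", "F"): {"insulin": (0.30, 0.25), "glucose": (95.0, 12.0)},
}


def gen_clinical(
    design: StudyDesign,
    group_means_sds: Optional[Mapping] = None,
    seed: int = 0,
):
    """Per-animal fasting insulin (uU/mL) and glucose (mg/dL) table."""
    spec = dict(group_means_sds or DEFAULT_CLINICAL)
    rng = np.random.default_rng(seed)
    bio = design.sample_table().query("role == 'biological'")
    rows = []
    for _, r in bio.iterrows():
        cell = spec[(r["group"], r["sex"])]
        ins = max(float(rng.normal(*cell["insulin"])), 0.05)
        glc = max(float(rng.normal(*cell["glucose"])), 5.0)
        if cell["insulin"][1] == 0:
            ins = cell["insulin"][0]
        if cell["glucose"][1] == 0:
            glc = cell["glucose"][0]
        rows.append((r["sample"], r["group"], r["sex"], ins, glc))
    return pd.DataFrame(
        rows, columns=["sample", "group", "sex", "insulin", "glucose"]
    )
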