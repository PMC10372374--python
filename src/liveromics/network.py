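"""Protein-protein interaction network statistics.

Covers the whole network procedure: loading STRING-style scored edge lists,
mapping dysregulated-protein seed lists onto the graph, largest-connected-
component (LCC) significance against random node sets, extraction of
significant cores, random-walk-with-restart (RWR) propagation and seed
expansion, Jaccard overlap and network proximity to disease gene sets with
a degree-matched null, and file-based over-representation analysis (ORA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests


def load_graph(
    edges: pd.DataFrame,
    score_min: float = 0.7,
    variant: str = "full",
) -> nx.Graph:
    """Build a simple scored graph from a (protein1, protein2, combined_score) table.

    Scores above 1 are taken to be on STRING's 0-1000 integer dialect and
    divided by 1000. Edges are kept iff score > ``score_min`` (strict);
    self-loops are dropped and duplicates (either direction) stored once.
    """
    e = edges.copy()
    scores = e["combined_score"].astype(float)
    if (scores > 1).any():
        scores = scores / 1000.0
    e["combined_score"] = scores
    g = nx.Graph(variant=variant, score_min=score_min)
    for u, v, s in e[["protein1", "protein2", "combined_score"]].itertuples(index=False):
        if u == v or s <= score_min:
            continue
        prev = g.edges[u, v]["combined_score"] if g.has_edge(u, v) else -1.0
        if s > prev:
            g.add_edge(str(u), str(v), combined_score=float(s))
    return g


@dataclass
class SeedSet:
    genes: List[str]
    direction: str = "all"  # up | down | all
    mapped: List[str] = field(default_factory=list)
    unmapped: List[str] = field(default_factory=list)

    @property
    def coverage(self) -> float:
        return len(self.mapped) / len(self.genes) if self.genes else 0.0


def map_seeds(genes: Iterable[str], g: nx.Graph, direction: str = "all") -> SeedSet:
    """Case-insensitive symbol matching of a seed list onto graph nodes."""
    genes = list(genes)
    lookup = {str(n).upper(): n for n in g.nodes}
    mapped, unmapped = [], []
    for gene in genes:
        node = lookup.get(str(gene).upper())
        (mapped if node is not None else unmapped).append(
            node if node is not None else gene
        )
    return SeedSet(genes=genes, direction=direction, mapped=mapped, unmapped=unmapped)


def lcc_size(nodes: Iterable, g: nx.Graph) -> int:
    sub = g.subgraph([n for n in nodes if n in g])
    if sub.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(sub))


@dataclass
class LccResult:
    observed: int
    null_mean: float
    null_sd: float
    z: Optional[float]
    p_empirical: float
    p_normal: Optional[float]
    n_random: int
    seed: int


def lcc_zscore(
    seeds: SeedSet | Sequence[str],
    g: nx.Graph,
    n_random: int = 10000,
    seed: int = 0,
    size: Optional[int] = None,
    observed: Optional[int] = None,
) -> LccResult:
    """LCC size of the seed-induced subgraph vs uniform random node sets.

    The null draws ``n_random`` node sets of the same size uniformly without
    replacement and records their LCC sizes; z = (obs - mean)/SD and the
    empirical p uses the add-one estimator. ``size``/``observed`` allow
    scoring a component at a chosen set size (core significance).
    """
    mapped = seeds.mapped if isinstance(seeds, SeedSet) else list(seeds)
    if len(mapped) < 2:
        raise ValueError("need >= 2 mapped seeds")
    obs = lcc_size(mapped, g) if observed is None else observed
    k = len(mapped) if size is None else size
    nodes = np.array(sorted(g.nodes))
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for i in range(n_random):
        null[i] = lcc_size(rng.choice(nodes, k, replace=False), g)
    sd = float(null.std(ddof=0))
    z = (obs - null.mean()) / sd if sd > 0 else None
    if z is None:
        warnings.warn("null SD is 0; z undefined, empirical p only", stacklevel=2)
    p_emp = float((1 + np.sum(null >= obs)) / (1 + n_random))
    p_norm = float(stats.norm.sf(z)) if z is not None else None
    return LccResult(
        observed=int(obs),
        null_mean=float(null.mean()),
        null_sd=sd,
        z=None if z is None else float(z),
        p_empirical=p_emp,
        p_normal=p_norm,
        n_random=n_random,
        seed=seed,
    )


def extract_cores(
    seeds: SeedSet | Sequence[str],
    g: nx.Graph,
    min_size: int = 2,
    n_random: int = 1000,
    seed: int = 0,
) -> List[dict]:
    """Connected components of the seed-induced subgraph with significance.

    Each component of size >= ``min_size`` is scored by the LCC-style null at
    its own size (random sets of that size; statistic = their LCC size).
    """
    mapped = seeds.mapped if isinstance(seeds, SeedSet) else list(seeds)
    sub = g.subgraph([n for n in mapped if n in g])
    cores = []
    for i, comp in enumerate(
        sorted(nx.connected_components(sub), key=lambda c: (-len(c), sorted(c)))
    ):
        if len(comp) < min_size:
            continue
        res = lcc_zscore(
            sorted(comp), g, n_random=n_random, seed=seed + i, size=len(comp)
        )
        cores.append({"nodes": sorted(comp), "size": len(comp), "significance": res})
    return cores


def rwr(
    g: nx.Graph,
    seeds: Iterable,
    alpha: float = 0.9,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> pd.Series:
    """Random walk with restart: p <- alpha*p0 + (1-alpha)*W p.

    W is the column-normalized adjacency; p0 is uniform over the seeds.
    Columns of degree-0 nodes redistribute their mass to p0 (self-restart).
    Scores sum to 1 at every iteration; iteration stops when the L1 change
    falls below ``tol``.
    """
    seeds = [s for s in seeds]
    if not seeds:
        raise ValueError("empty seed set")
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    missing = [s for s in seeds if s not in idx]
    if missing:
        raise ValueError(f"seeds not in graph: {missing[:5]}")
    n = len(nodes)
    A = nx.to_scipy_sparse_array(g, nodelist=nodes, format="csc", dtype=float)
    deg = np.asarray(A.sum(axis=0)).ravel()
    dangling = deg == 0
    inv = np.where(dangling, 0.0, 1.0 / np.where(dangling, 1.0, deg))
    W = A @ sparse.diags(inv)
    p0 = np.zeros(n)
    for s in seeds:
        p0[idx[s]] = 1.0 / len(seeds)
    p = p0.copy()
    for _ in range(max_iter):
        dangling_mass = p[dangling].sum()
        p_new = alpha * p0 + (1 - alpha) * (W @ p + dangling_mass * p0)
        if np.abs(p_new - p).sum() < tol:
            p = p_new
            break
        p = p_new
    return pd.Series(p, index=nodes, name="rwr_score")


@dataclass
class ExpansionResult:
    seeds: List[str]
    added: List[str]
    coverage: float
    target_coverage: float
    capped: bool
    alpha: float

    @property
    def expanded(self) -> List[str]:
        return list(self.seeds) + list(self.added)


def seed_connectivity(seeds: Sequence, extra: Sequence, g: nx.Graph) -> float:
    """Fraction of seeds inside the LCC of the subgraph induced by seeds+extra."""
    nodes = set(seeds) | set(extra)
    sub = g.subgraph([n for n in nodes if n in g])
    if sub.number_of_nodes() == 0:
        return 0.0
    seed_set = set(seeds)
    best = 0
    for comp in nx.connected_components(sub):
        best = max(best, len(comp & seed_set))
    return best / len(seed_set) if seed_set else 0.0


def rwr_expand(
    g: nx.Graph,
    seeds: SeedSet | Sequence[str],
    alpha: float = 0.9,
    target_coverage: float = 0.9,
    max_additions: Optional[int] = None,
) -> ExpansionResult:
    """Greedy RWR-ranked expansion until >= ``target_coverage`` of the seeds
    sit in one connected component of the induced subgraph.

    Non-seed nodes are added one at a time in decreasing propagation score,
    ties broken by higher degree then lexicographic symbol. A configured
    additions cap stops early (flagged in the result).
    """
    mapped = seeds.mapped if isinstance(seeds, SeedSet) else list(seeds)
    scores = rwr(g, mapped, alpha=alpha)
    cov = seed_connectivity(mapped, [], g)
    added: List[str] = []
    if cov >= target_coverage:
        return ExpansionResult(mapped, added, cov, target_coverage, False, alpha)
    candidates = [n for n in scores.index if n not in set(mapped)]
    order = sorted(
        candidates, key=lambda n: (-scores[n], -g.degree[n], str(n))
    )
    cap = len(order) if max_additions is None else max_additions
    for node in order[:cap]:
        added.append(node)
        cov = seed_connectivity(mapped, added, g)
        if cov >= target_coverage:
            return ExpansionResult(mapped, added, cov, target_coverage, False, alpha)
    return ExpansionResult(mapped, added, cov, target_coverage, True, alpha)


def jaccard(s1: Iterable, s2: Iterable) -> float:
    a, b = set(s1), set(s2)
    union = a | b
    return len(a & b) / len(union) if union else 0.0


# ---------------------------------------------------------------------------
# network proximity
# ---------------------------------------------------------------------------


class DistanceEngine:
    """Cached sparse-graph shortest-path backend for repeated set queries."""

    def __init__(self, g: nx.Graph):
        self.nodes = sorted(g.nodes)
        self.idx = {n: i for i, n in enumerate(self.nodes)}
        self.csr = nx.to_scipy_sparse_array(
            g, nodelist=self.nodes, format="csr", dtype=float
        )

    def min_distances(self, targets: Sequence) -> np.ndarray:
        """Per-node minimum unweighted distance to the target set."""
        from scipy.sparse.csgraph import dijkstra

        return dijkstra(
            self.csr,
            directed=False,
            unweighted=True,
            indices=[self.idx[t] for t in targets],
            min_only=True,
        )


def closest_distance(
    g: nx.Graph | DistanceEngine,
    s1: Sequence,
    s2: Sequence,
    unreachable: str = "exclude",
) -> Tuple[float, int]:
    """d_c = mean over s1 of the minimum shortest-path distance into s2.

    Unreachable s1 nodes are excluded from the average by default (count
    returned); ``unreachable`` may also be a numeric penalty.
    """
    eng = g if isinstance(g, DistanceEngine) else DistanceEngine(g)
    dist = eng.min_distances(list(set(s2)))
    vals, n_unreachable = [], 0
    for u in s1:
        d = dist[eng.idx[u]]
        if np.isfinite(d):
            vals.append(float(d))
        else:
            n_unreachable += 1
            if unreachable != "exclude":
                vals.append(float(unreachable))
    if not vals:
        raise ValueError("no s1 node can reach s2")
    return float(np.mean(vals)), n_unreachable


def degree_bins(
    g: nx.Graph, min_bin_size: int = 100
) -> Dict[int, List]:
    """Logarithmic-width degree bins, merged upward until each holds
    >= ``min_bin_size`` candidate nodes (or the top bin is reached)."""
    by_bin: Dict[int, List] = {}
    for n in sorted(g.nodes):
        b = int(np.floor(np.log2(max(g.degree[n], 1))))
        by_bin.setdefault(b, []).append(n)
    merged: Dict[int, List] = {}
    keys = sorted(by_bin)
    carry: List = []
    for b in keys:
        cur = carry + by_bin[b]
        if len(cur) >= min_bin_size or b == keys[-1]:
            merged[b] = cur
            carry = []
        else:
            carry = cur
    if carry:  # leftovers merge downward into the top bin
        top = max(merged) if merged else 0
        merged.setdefault(top, [])
        merged[top] = merged[top] + carry
    # an undersized top bin merges into its predecessor
    if len(merged) > 1:
        top = max(merged)
        if len(merged[top]) < min_bin_size:
            rest = sorted(merged)[-2]
            merged[rest] = merged[rest] + merged.pop(top)
    return merged


def _bin_lookup(bins: Dict[int, List]) -> Dict:
    node_bin = {}
    for b, members in bins.items():
        for n in members:
            node_bin[n] = b
    return node_bin


def sample_degree_matched(
    nodes: Sequence, bins: Dict[int, List], rng: np.random.Generator
) -> List:
    """Random node set preserving the exact per-bin degree composition."""
    node_bin = _bin_lookup(bins)
    need: Dict[int, int] = {}
    for n in nodes:
        need[node_bin[n]] = need.get(node_bin[n], 0) + 1
    out: List = []
    for b, k in sorted(need.items()):
        out.extend(rng.choice(bins[b], size=k, replace=False).tolist())
    return out


@dataclass
class ProximityResult:
    d_observed: float
    null_mean: float
    null_sd: float
    z: Optional[float]
    p_empirical: float
    n_random: int
    seed: int
    n_unreachable: int
    min_bin_size: int
    null_distances: np.ndarray = field(repr=False, default=None)


def network_proximity(
    s1: Sequence,
    s2: Sequence,
    g: nx.Graph,
    n_random: int = 10000,
    seed: int = 0,
    min_bin_size: int = 100,
    unreachable: str = "exclude",
) -> ProximityResult:
    """Closest-distance proximity of s1 to s2 with a degree-matched null.

    Both sets are replaced, in every null draw, by random sets matching
    their exact degree-bin composition (log-width bins merged upward to
    >= ``min_bin_size`` candidates). Small distances mean proximal, so the
    empirical p counts null distances <= observed.
    """
    s1 = [n for n in s1 if n in g]
    s2 = [n for n in s2 if n in g]
    if not s1 or not s2:
        raise ValueError("both sets must map to the graph")
    eng = DistanceEngine(g)
    d_obs, n_unreach = closest_distance(eng, s1, s2, unreachable)
    bins = degree_bins(g, min_bin_size=min_bin_size)
    rng = np.random.default_rng(seed)
    null = np.empty(n_random)
    for i in range(n_random):
        r1 = sample_degree_matched(s1, bins, rng)
        r2 = sample_degree_matched(s2, bins, rng)
        try:
            null[i], _ = closest_distance(eng, r1, r2, unreachable)
        except ValueError:
            null[i] = np.nan
    ok = ~np.isnan(null)
    sd = float(null[ok].std(ddof=0))
    mean = float(null[ok].mean())
    z = (d_obs - mean) / sd if sd > 0 else None
    p_emp = float((1 + np.sum(null[ok] <= d_obs)) / (1 + ok.sum()))
    return ProximityResult(
        d_observed=d_obs,
        null_mean=mean,
        null_sd=sd,
        z=None if z is None else float(z),
        p_empirical=p_emp,
        n_random=n_random,
        seed=seed,
        n_unreachable=n_unreach,
        min_bin_size=min_bin_size,
        null_distances=null,
    )


# ---------------------------------------------------------------------------
# disease screening and ORA
# ---------------------------------------------------------------------------


def filter_catalog(catalog: pd.DataFrame, gda_min: float = 0.3) -> pd.DataFrame:
    """Keep associations with GDA score strictly above ``gda_min``;
    duplicate (disease, gene) pairs collapse to their maximum score."""
    c = (
        catalog.groupby(["disease_id", "gene"], as_index=False)["gda_score"].max()
    )
    return c[c["gda_score"] > gda_min].reset_index(drop=True)


def disease_screen(
    core: Sequence,
    catalog: pd.DataFrame,
    g: nx.Graph,
    gda_min: float = 0.3,
    n_random: int = 1000,
    seed: int = 0,
    min_bin_size: int = 100,
) -> pd.DataFrame:
    """Jaccard and network proximity of a core against every catalogued disease.

    The catalogue is filtered at GDA > ``gda_min``; per disease, the Jaccard
    index of the raw gene sets and the proximity z/p of the mapped sets are
    computed, and empirical proximity p-values are BH-adjusted across
    diseases.
    """
    filtered = filter_catalog(catalog, gda_min)
    core = list(core)
    rows = []
    for i, (did, sub) in enumerate(sorted(filtered.groupby("disease_id"))):
        genes = sorted(sub["gene"].unique())
        jac = jaccard(core, genes)
        mapped = [x for x in genes if x in g]
        if mapped and [n for n in core if n in g]:
            prox = network_proximity(
                core, mapped, g, n_random=n_random, seed=seed + i,
                min_bin_size=min_bin_size,
            )
            rows.append(
                (did, len(genes), jac, prox.d_observed, prox.z, prox.p_empirical)
            )
        else:
            rows.append((did, len(genes), jac, np.nan, np.nan, np.nan))
    out = pd.DataFrame(
        rows, columns=["disease_id", "n_genes", "jaccard", "d_c", "z", "p_empirical"]
    ).set_index("disease_id")
    ok = out["p_empirical"].notna()
    out["p_adjusted"] = np.nan
    if ok.any():
        out.loc[ok, "p_adjusted"] = multipletests(
            out.loc[ok, "p_empirical"], method="fdr_bh"
        )[1]
    return out


def ora(
    query: Iterable,
    universe: Iterable,
    gene_sets: Dict[str, Sequence],
    p_adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in GMT gene sets.

    Per set: k = |query & set|, p = P(X >= k) for X ~ Hypergeom(|universe|,
    |set & universe|, |query|); enrichment = (k/|query|)/(K/|universe|).
    """
    query = set(query)
    universe = set(universe)
    if not query <= universe:
        query = query & universe
    M, n = len(universe), len(query)
    if n == 0:
        raise ValueError("empty query after intersecting with the universe")
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        K = len(members)
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if K else 1.0
        enr = (k / n) / (K / M) if K else 0.0
        rows.append((name, K, k, enr, p))
    out = pd.DataFrame(
        rows, columns=["gene_set", "set_size", "overlap", "enrichment", "p"]
    ).set_index("gene_set")
    out["p_adjusted"] = multipletests(out["p"], method=p_adjust)[1]
    return out.sort_values("p")
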