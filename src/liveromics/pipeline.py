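"""End-to-end orchestration of the synthetic multi-omics analysis.

``run_all`` executes the configured stages in method order — proteome-style
and metabolome-style differential abundance, lipidomics QC, multivariate
statistics and the network procedure — on synthetic inputs with known
planted truth, writing per-stage outputs plus a manifest (parameters,
per-stage seeds, input hashes) that suffices to re-execute the run.

Per-stage sub-seeds derive from the global seed by hashing the stage name,
so adding or removing a stage never shifts another stage's random stream.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import diffstats, io, lipidqc, multivar, network, synth
from .design import StudyDesign


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable, stage-local sub-seed (counter-based, below 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/synthetic"
    n_features: int = 300
    n_metabolites: int = 100
    lipid_species: int = 1204
    lipid_planted: tuple = synth.DEFAULT_PLANTED_COUNTS
    ppi_nodes: int = 2000
    ppi_module_size: int = 10
    n_diseases: int = 50
    n_random_network: int = 1000
    run_lipidomics: bool = True
    run_network: bool = True
    anova_ss_type: str = "II"
    p_max: float = 0.05
    min_fold: float = 1.5

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        if isinstance(cfg.lipid_planted, list):
            cfg.lipid_planted = tuple(cfg.lipid_planted)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["lipid_planted"] = list(d["lipid_planted"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def validate_inputs(matrix: pd.DataFrame, design: pd.DataFrame) -> list:
    """Consistency checks before any computation; returns a list of issues."""
    issues = []
    if matrix.index.has_duplicates:
        dup = matrix.index[matrix.index.duplicated()].unique().tolist()
        issues.append(f"duplicate feature IDs: {dup[:5]}")
    known = set(design["sample"])
    missing = [c for c in matrix.columns if c not in known]
    if missing:
        issues.append(f"samples missing from design: {missing[:5]}")
    return issues


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> Dict:
    """Execute the configured synthetic pipeline; returns the report bundle.

    The planted PPI module genes double as group-affected proteome features,
    so the differential-abundance branch feeds the network branch seeds with
    known truth. Partial failures stop only the dependent branch.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = StudyDesign()
    dtab = design.sample_table()
    report: Dict = {"stages": {}, "seeds": {}, "issues": {}}
    manifest: Dict = {"config": asdict(config), "files": {}, "seeds": {}}
    manifest["config"]["lipid_planted"] = list(config.lipid_planted)

    # --- network inputs first: module genes seed the proteome effects -----
    graph = None
    module_genes: list = []
    if config.run_network:
        s = stage_seed(config.seed, "ppi")
        report["seeds"]["ppi"] = manifest["seeds"]["ppi"] = s
        graph, ppi_truth = synth.gen_ppi(
            n_nodes=config.ppi_nodes,
            planted_modules=((config.ppi_module_size, 0.9),),
            seed=s,
        )
        module_genes = ppi_truth.index[ppi_truth["module"] == 0].tolist()
        io.write_edge_list(synth.ppi_edge_table(graph), out / "ppi_edges.tsv")

    # --- proteome-style matrix + differential abundance -------------------
    s = stage_seed(config.seed, "proteome")
    report["seeds"]["proteome"] = manifest["seeds"]["proteome"] = s
    feature_names = (
        sorted(graph.nodes)[: config.n_features]
        if graph is not None
        else None
    )
    if feature_names is not None:
        # planted module genes must be present in the matrix
        feature_names = sorted(set(feature_names) | set(module_genes))[
            : max(config.n_features, len(module_genes))
        ]
        feature_names = sorted(set(feature_names) | set(module_genes))
    spec = synth.EffectSpec(
        n_features=len(feature_names) if feature_names else config.n_features
    )
    prot, prot_truth = synth.gen_omics_matrix(
        design, spec, seed=s, feature_names=feature_names,
        group_features=module_genes or None,
    )
    issues = validate_inputs(prot, dtab)
    if issues:
        raise ValueError(f"proteome validation failed: {issues}")
    stats_tbl, summary = diffstats.differential_abundance(
        prot, dtab, ss_type=config.anova_ss_type,
        p_max=config.p_max, min_fold=config.min_fold,
    )
    io.write_matrix(prot, out / "proteome.tsv")
    stats_tbl.to_csv(out / "proteome_stats.tsv", sep="\t")
    report["stages"]["proteome"] = {
        "summary": summary,
        "n_planted_group": int((prot_truth["effect"] == "group").sum()),
    }

    # --- metabolome-style matrix, OPLS-DA and co-inertia -------------------
    s = stage_seed(config.seed, "metabolome")
    report["seeds"]["metabolome"] = manifest["seeds"]["metabolome"] = s
    met_spec = synth.EffectSpec(
        n_features=config.n_metabolites, frac_group_affected=0.2
    )
    met, met_truth = synth.gen_omics_matrix(design, met_spec, seed=s)
    io.write_matrix(met, out / "metabolome.tsv")
    bio = dtab[dtab["role"] == "biological"].set_index("sample")
    labels = bio.loc[met.columns, "group"]
    scaled = multivar.scale_matrix(met.T, log2=True, scaling="pareto")
    opls = multivar.opls_da(scaled, labels.to_numpy())
    prot_scaled = multivar.scale_matrix(prot.dropna(axis=0).T, log2=True, scaling="pareto")
    cia = multivar.coinertia(
        prot_scaled, scaled, n_perm=200, seed=stage_seed(config.seed, "cia")
    )
    report["stages"]["multivar"] = {
        "opls": {"r2x": opls.r2x, "r2y": opls.r2y, "q2": opls.q2,
                 "n_ortho": opls.n_ortho},
        "cia": {"rv": cia.rv, "perm_p": cia.perm_p,
                "axis1_frac": float(cia.axis_fractions[0])},
    }

    # --- lipidomics QC -----------------------------------------------------
    if config.run_lipidomics:
        s = stage_seed(config.seed, "lipidome")
        report["seeds"]["lipidome"] = manifest["seeds"]["lipidome"] = s
        raw, lipid_truth = synth.gen_lipid_raw(
            design, n_species=config.lipid_species,
            planted_counts=tuple(config.lipid_planted), seed=s,
        )
        qc = lipidqc.run_qc(raw, dtab)
        io.write_matrix(raw, out / "lipidome_raw.tsv")
        io.write_matrix(qc.table, out / "lipidome_clean.tsv")
        io.write_json(qc.to_dict(), out / "lipid_qc_report.json")
        report["stages"]["lipidomics"] = qc.to_dict()
        del report["stages"]["lipidomics"]["removed"]

    # --- network branch -----------------------------------------------------
    if config.run_network and graph is not None:
        s = stage_seed(config.seed, "network")
        report["seeds"]["network"] = manifest["seeds"]["network"] = s
        de_up = stats_tbl.index[
            stats_tbl["sig_group"] & (stats_tbl["l2fc"] > 0)
        ].tolist()
        de_all = stats_tbl.index[stats_tbl["sig_group"]].tolist()
        seeds = network.map_seeds(de_all, graph)
        lcc = network.lcc_zscore(
            seeds, graph, n_random=config.n_random_network, seed=s
        )
        cores = network.extract_cores(
            seeds, graph, n_random=config.n_random_network, seed=s + 1
        )
        catalog, _ = synth.gen_disease_catalog(
            config.n_diseases,
            sorted(graph.nodes),
            overlap_spec={0: (module_genes, max(2, len(module_genes) // 2))},
            seed=stage_seed(config.seed, "diseases"),
        )
        io.write_disease_table(catalog, out / "diseases.tsv")
        core_nodes = cores[0]["nodes"] if cores else seeds.mapped
        screen = network.disease_screen(
            core_nodes, catalog, graph,
            n_random=min(config.n_random_network, 200), seed=s + 2,
        )
        screen.to_csv(out / "disease_screen.tsv", sep="\t")
        report["stages"]["network"] = {
            "n_seeds": len(seeds.mapped),
            "n_up": len(de_up),
            "coverage": seeds.coverage,
            "lcc": {"observed": lcc.observed, "z": lcc.z, "p": lcc.p_empirical},
            "n_cores": len(cores),
            "top_disease": screen["p_adjusted"].idxmin()
            if screen["p_adjusted"].notna().any() else None,
        }

    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        manifest["files"][f.name] = _sha256(f)
    io.write_json(manifest, out / "manifest.json")
    io.write_json(report, out / "report.json")
    return report
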