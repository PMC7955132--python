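"""End-to-end pipeline orchestration and run manifests.

Stages: preprocessing -> per-condition dual-metric networks -> combination
-> fusion -> backbone -> communities -> IC genes -> gene-set catalog ->
classification -> Cox screening -> enrichment.  Every intermediate is
serialized as plain text (TSV / JSON) under the output directory, and a
manifest records per-stage counts, parameters and seeds so identical
config + seed reproduces identical artifacts.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coexpression import WeightedGeneNetwork, build_condition_network
from .fusion import (
    DEFAULT_DISPARITY_PERCENTILE,
    DEFAULT_IDENTITY_MIXING,
    DEFAULT_K,
    DEFAULT_MIN_SIZE_FRACTION,
    DEFAULT_TOLERANCE,
    FusedNetwork,
    detect_communities,
    disparity_filter,
    partition_table,
    select_ic_genes,
    snf_fuse,
)
from .matrix import ExpressionMatrix, log_transform, read_annotation, write_annotation
from .preprocess import DEFAULT_THRESHOLD, preprocess_pair
from .simulate import (
    SimulationConfig,
    PlantedModule,
    generate_annotations,
    generate_expression,
    generate_survival,
    plan_roles,
    read_survival,
    write_survival,
)
from .survival_enrichment import cox_multivariate, cox_univariate_screen, fisher_enrichment
from .validation import build_catalog, classify_and_score, compare_gene_sets, de_genes

# stage names -> fixed index used to fan the master seed out deterministically
STAGE_SEEDS = {
    "simulate": 0,
    "networks_normal": 1,
    "networks_cancer": 2,
    "communities": 3,
    "catalog": 4,
    "classification": 5,
    "survival": 6,
    "annotations": 7,
}


def stage_seed(master: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(master), STAGE_SEEDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Resolved configuration of a full pipeline run."""

    output_dir: str = "run"
    seed: int = 0
    # exactly one of: simulation config, or explicit input paths
    simulation: SimulationConfig | None = None
    expression_normal: str | None = None
    expression_cancer: str | None = None
    annotation: str | None = None
    survival: str | None = None
    knowledge_flags: str | None = None
    # stage parameters
    zfpkm_threshold: float = DEFAULT_THRESHOLD
    euclidean_percentile: float = 99.0
    n_shuffles: int = 10
    null_mode: str = "pooled"
    snf_k: int = DEFAULT_K
    snf_tolerance: float = DEFAULT_TOLERANCE
    snf_max_iter: int = 50
    snf_identity_mixing: float = DEFAULT_IDENTITY_MIXING
    disparity_percentile: float = DEFAULT_DISPARITY_PERCENTILE
    community_resolution: float = 1.0
    min_size_fraction: float = DEFAULT_MIN_SIZE_FRACTION
    de_alpha: float = 0.05
    de_lfc: float = 2.0
    n_repetitions: int = 100
    rf_estimators: int = 500
    lasso_policy: str = "cv_1se"
    # synthetic-mode extras
    survival_drivers: list[str] | None = None
    survival_betas: list[float] | None = None
    censor_rate: float = 0.3
    annotation_positive_fraction: float = 0.05
    annotation_enrichment_odds: float = 5.0

    def __post_init__(self) -> None:
        has_paths = self.expression_normal is not None
        if (self.simulation is None) == (not has_paths):
            raise ValueError(
                "exactly one of a simulation block or explicit input paths is required"
            )


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    sim = raw.pop("simulation", None)
    if sim is not None:
        modules = [PlantedModule(**m) for m in sim.pop("modules", [])]
        sim = SimulationConfig(modules=modules, **sim)
    return RunConfig(simulation=sim, **raw)


def write_network(net: WeightedGeneNetwork, path: Path, meta: dict, graphml: bool = False) -> None:
    net.to_tsv(path)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    if graphml:
        g = nx.Graph()
        edges = net.edge_list()
        for row in edges.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, weight=float(row.weight))
        nx.write_graphml(g, path.with_suffix(".graphml"))


def compute_topology(edges: pd.DataFrame, subset: set[str] | None = None) -> dict:
    """Node/edge counts and average degree 2|E|/|V| of an edge list.

    With ``subset`` the numbers are additionally computed on the induced
    subgraph.
    """
    if edges.empty:
        raise ValueError("network is empty")
    nodes = set(edges["gene_a"]) | set(edges["gene_b"])
    out = {
        "n_nodes": len(nodes),
        "n_edges": len(edges),
        "average_degree": 2.0 * len(edges) / len(nodes),
    }
    if subset is not None:
        sub = edges[edges["gene_a"].isin(subset) & edges["gene_b"].isin(subset)]
        sub_nodes = set(sub["gene_a"]) | set(sub["gene_b"])
        out["subset"] = {
            "n_nodes": len(sub_nodes),
            "n_edges": len(sub),
            "average_degree": (2.0 * len(sub) / len(sub_nodes)) if sub_nodes else 0.0,
        }
    return out


def extract_ic(
    normal: ExpressionMatrix,
    cancer: ExpressionMatrix,
    annotation: pd.Series,
    seed: int = 0,
    zfpkm_threshold: float = DEFAULT_THRESHOLD,
    euclidean_percentile: float = 99.0,
    n_shuffles: int = 10,
    null_mode: str = "pooled",
    snf_k: int = DEFAULT_K,
    snf_tolerance: float = DEFAULT_TOLERANCE,
    snf_max_iter: int = 50,
    snf_identity_mixing: float = DEFAULT_IDENTITY_MIXING,
    disparity_percentile: float = DEFAULT_DISPARITY_PERCENTILE,
    community_resolution: float = 1.0,
    min_size_fraction: float = DEFAULT_MIN_SIZE_FRACTION,
) -> dict:
    """Network stages only: preprocessing -> networks -> fusion -> IC genes.

    Returns a dict with the filtered matrices, per-condition networks, the
    disparity-filtered fused network and the community partition (with the
    IC selection applied).  This is the pipeline's core path without the
    classification / survival / enrichment stages.
    """
    normal_f, cancer_f = preprocess_pair(normal, cancer, annotation, threshold=zfpkm_threshold)
    nets = {}
    for cond, expr in (("normal", normal_f), ("cancer", cancer_f)):
        nets[cond] = build_condition_network(
            log_transform(expr),
            euclidean_percentile=euclidean_percentile,
            n_shuffles=n_shuffles,
            seed=stage_seed(seed, f"networks_{cond}"),
            null_mode=null_mode,
        )
    fused = snf_fuse(
        nets["normal"]["combined"],
        nets["cancer"]["combined"],
        K=snf_k,
        tolerance=snf_tolerance,
        max_iter=snf_max_iter,
        identity_mixing=snf_identity_mixing,
    )
    fused = disparity_filter(fused, percentile=disparity_percentile)
    partition = detect_communities(
        fused, resolution=community_resolution, seed=stage_seed(seed, "communities")
    )
    partition = select_ic_genes(partition, min_size_fraction)
    return {
        "normal_filtered": normal_f,
        "cancer_filtered": cancer_f,
        "networks": nets,
        "fused": fused,
        "partition": partition,
        "ic_genes": partition.ic_genes,
    }


def _load_inputs(config: RunConfig, outdir: Path) -> dict:
    """Simulate or read the input artifacts; synthetic inputs are serialized."""
    if config.simulation is not None:
        sim = config.simulation
        normal, cancer = generate_expression(sim)
        annotation = sim.biotypes()
        roles = plan_roles(sim)
        drivers = config.survival_drivers
        betas = config.survival_betas
        if drivers is None:
            drivers = (sim.modules[0].member_genes[:5] if sim.modules else [])
            betas = [0.5] * len(drivers)
        survival = generate_survival(
            cancer,
            drivers,
            betas or [],
            censor_rate=config.censor_rate,
            seed=stage_seed(config.seed, "survival"),
        )
        flags = generate_annotations(
            normal.genes,
            config.annotation_positive_fraction,
            roles.module_genes,
            config.annotation_enrichment_odds,
            seed=stage_seed(config.seed, "annotations"),
        )
        normal.to_tsv(outdir / "expression_normal.tsv")
        cancer.to_tsv(outdir / "expression_cancer.tsv")
        write_annotation(annotation, outdir / "annotation.tsv")
        write_survival(survival, outdir / "survival.tsv")
        flags.rename_axis("gene_id").to_frame().to_csv(outdir / "knowledge_flags.tsv", sep="\t")
        truth = {
            "module_genes": roles.module_genes,
            "de_genes": roles.de_genes,
            "noise_genes": roles.noise_genes,
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
    else:
        annotation = read_annotation(config.annotation)
        normal = ExpressionMatrix.from_tsv(config.expression_normal, annotation, "normal")
        cancer = ExpressionMatrix.from_tsv(config.expression_cancer, annotation, "cancer")
        survival = read_survival(config.survival) if config.survival else None
        flags = None
        if config.knowledge_flags:
            df = pd.read_csv(config.knowledge_flags, sep="\t", index_col=0)
            flags = df.iloc[:, 0]
        truth = None
    return {
        "normal": normal,
        "cancer": cancer,
        "annotation": annotation,
        "survival": survival,
        "flags": flags,
        "truth": truth,
    }


def _single_measure_ic(
    nets_n: dict,
    nets_c: dict,
    measure: str,
    config: RunConfig,
) -> set[str]:
    """IC genes of a single-measure (euclidean- or pearson-only) pipeline.

    The per-condition single-measure networks are fused, filtered and
    clustered exactly like the combined ones; pearson weights enter as
    absolute values.
    """
    wn, wc = nets_n[measure], nets_c[measure]
    an = np.abs(wn.weights)
    ac = np.abs(wc.weights)
    try:
        fused = snf_fuse(
            an, ac, K=config.snf_k, tolerance=config.snf_tolerance,
            max_iter=config.snf_max_iter, genes=wn.genes,
            identity_mixing=config.snf_identity_mixing,
        )
        fused = disparity_filter(fused, percentile=config.disparity_percentile)
        if fused.backbone is None or fused.backbone.empty:
            return set()
        partition = detect_communities(
            fused,
            resolution=config.community_resolution,
            seed=stage_seed(config.seed, "communities"),
        )
        partition = select_ic_genes(partition, config.min_size_fraction)
        return partition.ic_genes
    except (ValueError, RuntimeError):
        return set()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "config": _config_dict(config),
        "stages": {},
    }

    inputs = _load_inputs(config, outdir)
    normal, cancer = inputs["normal"], inputs["cancer"]

    # --- preprocessing -------------------------------------------------
    normal_f, cancer_f = preprocess_pair(
        normal, cancer, inputs["annotation"], threshold=config.zfpkm_threshold
    )
    normal_f.to_tsv(outdir / "filtered_normal.tsv")
    cancer_f.to_tsv(outdir / "filtered_cancer.tsv")
    manifest["stages"]["preprocessing"] = {
        "original_genes": normal.n_genes,
        "filtered_genes": normal_f.n_genes,
    }

    # --- per-condition networks ----------------------------------------
    # networks are built on the log2(FPKM + 1) scale
    nets = {}
    for cond, expr in (("normal", normal_f), ("cancer", cancer_f)):
        built = build_condition_network(
            log_transform(expr),
            euclidean_percentile=config.euclidean_percentile,
            n_shuffles=config.n_shuffles,
            seed=stage_seed(config.seed, f"networks_{cond}"),
            null_mode=config.null_mode,
        )
        nets[cond] = built
        for measure in ("euclidean", "pearson", "combined"):
            net = built[measure]
            write_network(
                net,
                outdir / f"network_{cond}_{measure}.tsv",
                {
                    "measure": measure,
                    "condition": cond,
                    "n_edges": net.n_edges,
                    "euclidean_percentile": config.euclidean_percentile,
                    "null_bounds": [built["bounds"].lower, built["bounds"].upper],
                },
            )
        manifest["stages"][f"networks_{cond}"] = {
            "euclidean_edges": built["euclidean"].n_edges,
            "pearson_edges": built["pearson"].n_edges,
            "combined_edges": built["combined"].n_edges,
            "null_bounds": [built["bounds"].lower, built["bounds"].upper],
        }

    # --- fusion ---------------------------------------------------------
    fused = snf_fuse(
        nets["normal"]["combined"],
        nets["cancer"]["combined"],
        K=config.snf_k,
        tolerance=config.snf_tolerance,
        max_iter=config.snf_max_iter,
        identity_mixing=config.snf_identity_mixing,
    )
    fused = disparity_filter(fused, percentile=config.disparity_percentile)
    fused.backbone.to_csv(outdir / "backbone.tsv", sep="\t", index=False)
    partition = detect_communities(
        fused,
        resolution=config.community_resolution,
        seed=stage_seed(config.seed, "communities"),
    )
    partition = select_ic_genes(partition, config.min_size_fraction)
    partition_table(partition).to_csv(outdir / "communities.tsv", sep="\t", index=False)
    ic = partition.ic_genes
    backbone_genes = set(fused.backbone_genes())
    topo = compute_topology(fused.backbone, subset=ic)

    def _edge_set(net):
        df = net.edge_list()
        return {(a, b) for a, b in zip(df["gene_a"], df["gene_b"])}

    merged_edges = _edge_set(nets["normal"]["combined"]) | _edge_set(nets["cancer"]["combined"])
    manifest["stages"]["fusion"] = {
        "merged_edges": len(merged_edges),
        "t_star": fused.t_star,
        "backbone_edges": int(len(fused.backbone)),
        "backbone_genes": len(backbone_genes),
        "alpha_cutoff": fused.alpha_cutoff,
        "n_communities": len(partition.sizes()),
        "modularity": partition.modularity,
        "ic_genes": len(ic),
        "topology": topo,
    }

    # --- gene-set catalog and classification ---------------------------
    eucl_ic = _single_measure_ic(nets["normal"], nets["cancer"], "euclidean", config)
    pears_ic = _single_measure_ic(nets["normal"], nets["cancer"], "pearson", config)
    de_table = de_genes(
        normal_f.values, cancer_f.values, alpha=config.de_alpha, lfc=config.de_lfc
    )
    de_table.to_csv(outdir / "de_genes.tsv", sep="\t")
    de_set = set(de_table.index[de_table["is_de"]])

    all_genes = normal_f.genes
    X = pd.DataFrame(
        np.log2(
            np.hstack([normal_f.values.to_numpy(), cancer_f.values.to_numpy()]).T + 1.0
        ),
        index=normal_f.samples + cancer_f.samples,
        columns=all_genes,
    )
    labels = np.array([0] * normal_f.n_samples + [1] * cancer_f.n_samples)
    catalog = build_catalog(
        all_genes,
        ic & set(all_genes),
        eucl_ic & set(all_genes),
        pears_ic & set(all_genes),
        de_set,
        X,
        labels,
        seed=stage_seed(config.seed, "catalog"),
        lasso_policy=config.lasso_policy,
    )
    for name, s in {**catalog.sets, **{f"{k}_L": v for k, v in catalog.reduced.items()}}.items():
        (outdir / f"geneset_{name}.txt").write_text("\n".join(sorted(s)) + "\n")
    catalog.intersections().to_csv(outdir / "geneset_intersections.tsv", sep="\t", index=False)

    clf_seed = stage_seed(config.seed, "classification")
    distributions = {}
    for name, s in catalog.reduced.items():
        if not s:
            continue
        distributions[name] = classify_and_score(
            X[sorted(s)],
            labels,
            n_repetitions=config.n_repetitions,
            seed=clf_seed,
            n_estimators=config.rf_estimators,
        )
    long = pd.concat(
        [d.assign(set=n) for n, d in distributions.items()], ignore_index=True
    )
    long.to_csv(outdir / "classification_metrics.tsv", sep="\t", index=False)
    comparison = None
    if "IC" in distributions:
        comparison = compare_gene_sets(
            distributions["IC"], {n: d for n, d in distributions.items() if n != "IC"}
        )
        comparison.to_csv(outdir / "classification_comparison.tsv", sep="\t", index=False)
    manifest["stages"]["validation"] = {
        "set_sizes": {n: len(s) for n, s in catalog.sets.items()},
        "reduced_sizes": {n: len(s) for n, s in catalog.reduced.items()},
        "mean_auc": {n: float(d["auc"].mean()) for n, d in distributions.items()},
    }

    # --- survival -------------------------------------------------------
    if inputs["survival"] is not None:
        surv = inputs["survival"]
        results = {}
        for name, s in (("IC", ic & set(all_genes)), ("DE", de_set)):
            if not s:
                continue
            screen = cox_univariate_screen(cancer_f.values, surv, sorted(s))
            screen.to_csv(outdir / f"cox_screen_{name}.tsv", sep="\t")
            passed = sorted(screen.index[screen["passes"]])
            entry = {"screened": len(screen), "passing": len(passed)}
            if passed:
                multi = cox_multivariate(cancer_f.values, surv, passed)
                multi.baseline_survival.to_csv(
                    outdir / f"survival_curve_{name}.tsv", sep="\t", index=False
                )
                entry["concordance"] = multi.concordance
                entry["concordance_se"] = multi.concordance_se
            results[name] = entry
        manifest["stages"]["survival"] = results

    # --- enrichment -----------------------------------------------------
    if inputs["flags"] is not None and ic:
        universe = set(all_genes)
        enr = fisher_enrichment(ic & universe, universe, inputs["flags"], source="knowledge")
        pd.DataFrame([asdict_enrichment(enr)]).to_csv(
            outdir / "enrichment.tsv", sep="\t", index=False
        )
        manifest["stages"]["enrichment"] = asdict_enrichment(enr)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest


def asdict_enrichment(enr) -> dict:
    return {
        "source": enr.source,
        "flagged_in_ic": enr.flagged_in_ic,
        "unflagged_in_ic": enr.unflagged_in_ic,
        "flagged_outside": enr.flagged_outside,
        "unflagged_outside": enr.unflagged_outside,
        "odds_ratio": enr.odds_ratio,
        "p_value": enr.p_value,
    }


def _config_dict(config: RunConfig) -> dict:
    out = {}
    for key, value in asdict(config).items():
        out[key] = value
    return out
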