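"""End-to-end orchestration: simulate -> filter -> adjust -> features ->
train (both representations) -> overlap -> hub-cluster per class.

Every stage writes its artifact into the run directory; a JSON manifest
records the config, per-stage shapes, and derived seeds, and a summary JSON
collects the headline numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as ehio
from .features import gene_counts
from .filtering import FilterThresholds, build_genotype_matrix, filter_calls, rejection_counts
from .hubclust import (
    carrier_sets,
    cut_clusters,
    distance_matrix,
    plot_dendrogram,
    rank_clusters,
    to_newick,
    ward_linkage,
)
from .model import balance_and_split, cross_validate, evaluate, important_genes, overlap_genes, train_regressor
from .simulate import CLASSES, SimulationConfig, simulate_cohorts
from .stratify import adjust_dataset, compute_axes

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the run seed and the stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


@dataclass
class RunConfig:
    """Schema-validated pipeline settings; defaults mirror the printed
    analysis settings (MAF 0.01, reads 4/10/90, 4 axes, 70:30, 5-fold CV,
    cap +/-4)."""

    simulation: dict = field(default_factory=dict)
    max_maf: float = 0.01
    min_alt_reads: int = 4
    min_depth: int = 10
    min_gq: int = 90
    n_axes: int = 4
    adjust_mode: str = "residual_plus_intercept"
    train_fraction: float = 0.70
    selection: str = "first_n"
    cv_folds: int = 5
    hyperparams: dict | None = None
    cluster_k: int | str = "auto"
    cluster_k_max: int = 6
    seed: int = 0

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            max_maf=self.max_maf,
            min_alt_reads=self.min_alt_reads,
            min_depth=self.min_depth,
            min_gq=self.min_gq,
        )

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", stage_seed(self.seed, "simulate"))
        for key in ("variants_per_gene", "maf_range"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        return SimulationConfig(**sim)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline, writing artifacts and a manifest to outdir."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(asdict(config)), "stages": {}}
    summary: dict = {}

    def stage(name: str, **info) -> None:
        manifest["stages"][name] = info
        logger.info("stage %s: %s", name, info)

    # 1. simulate
    sim_cfg = config.simulation_config()
    calls, truth = simulate_cohorts(sim_cfg)
    ehio.write_calls_tsv(calls, out / "calls.tsv")
    truth.to_json(out / "truth.json")
    stage("simulate", n_calls=len(calls), n_samples=len(truth.sample_ids), seed=sim_cfg.seed)

    # 2. filter
    thresholds = config.thresholds()
    rejections = rejection_counts(calls, thresholds)
    filtered = filter_calls(calls, thresholds)
    ehio.write_calls_tsv(filtered, out / "filtered_calls.tsv")
    stage("filter", n_calls=len(filtered), rejections=rejections)

    # 3. genotype matrix
    labels_map = dict(zip(truth.sample_ids, truth.class_labels))
    G = build_genotype_matrix(filtered, truth.sample_ids, labels_map)
    ehio.write_genotype_matrix(G, out / "genotype_matrix.tsv", out / "variant_gene_map.tsv")
    stage("matrix", n_samples=G.n_samples, n_variants=G.n_variants)

    # 4. stratification adjustment
    axes = compute_axes(G, n_axes=config.n_axes)
    np.savetxt(out / "axes_scores.tsv", axes.scores, delimiter="\t")
    A = adjust_dataset(G, axes, mode=config.adjust_mode)
    ehio.write_adjusted_matrix(A, out / "adjusted_matrix.tsv")
    stage("adjust", n_axes=axes.n_axes, eigenvalues=[float(e) for e in axes.eigenvalues])

    # 5. gene-level features
    C = gene_counts(A)
    ehio.write_gene_counts(C, out / "gene_counts.tsv")
    stage("features", n_genes=len(C.gene_ids))

    # 6. train both representations
    split = balance_and_split(
        A.labels,
        train_fraction=config.train_fraction,
        seed=stage_seed(config.seed, "split"),
        selection=config.selection,
    )
    stage(
        "split",
        per_class_train=split.per_class_train,
        per_class_test=split.per_class_test,
    )
    gene_lists: dict[str, list[str]] = {}
    for kind, X, names in (
        ("snv", A.values, A.feature_ids),
        ("gene", C.values, C.gene_ids),
    ):
        model_seed = stage_seed(config.seed, f"train_{kind}")
        booster = train_regressor(
            X[split.train_idx],
            A.adjusted_phenotype[split.train_idx],
            names,
            hyperparams=config.hyperparams,
            seed=model_seed,
        )
        report = evaluate(booster, X[split.test_idx], A.labels[split.test_idx])
        report.important_genes = important_genes(
            booster, feature_kind=kind, variant_to_gene=A.variant_to_gene
        )
        gene_lists[kind] = report.important_genes
        (out / f"model_{kind}_report.json").write_text(json.dumps(report.to_dict(), indent=1))
        _write_gene_list(report.important_genes, out / f"important_genes_{kind}.tsv")
        summary[f"{kind}_test"] = report.to_dict()
        if config.cv_folds >= 2:
            keep = np.concatenate([split.train_idx, split.test_idx])
            cv = cross_validate(
                X[keep],
                A.adjusted_phenotype[keep],
                A.labels[keep],
                names,
                k=config.cv_folds,
                seed=stage_seed(config.seed, f"cv_{kind}"),
                hyperparams=config.hyperparams,
            )
            (out / f"model_{kind}_cv.json").write_text(json.dumps(cv.to_dict(), indent=1))
            summary[f"{kind}_cv"] = {
                "accuracy": cv.accuracy,
                "precision": cv.precision,
                "recall": cv.recall,
                "nir": cv.nir,
            }
        stage(f"train_{kind}", params=booster.params, n_important=len(report.important_features))

    # 7. overlap
    overlap = overlap_genes(gene_lists["snv"], gene_lists["gene"])
    _write_gene_list(overlap, out / "overlapping_genes.tsv")
    summary["n_overlapping_genes"] = len(overlap)
    stage("overlap", n_genes=len(overlap))

    # 8. hub clustering per class
    summary["hub"] = {}
    for cls in CLASSES:
        sets = carrier_sets(C, cls, gene_subset=[g for g in overlap if g in C.gene_ids])
        if len(sets.sets) < 2:
            logger.warning("class %s: fewer than 2 genes with carriers; hub stage skipped", cls)
            continue
        genes, D = distance_matrix(sets)
        tree = ward_linkage(D, leaf_labels=genes)
        np.savetxt(out / f"linkage_{cls}.tsv", tree.merges, delimiter="\t")
        (out / f"dendrogram_{cls}.nwk").write_text(to_newick(tree))
        plot_dendrogram(tree, str(out / f"dendrogram_{cls}.png"))
        assignments = cut_clusters(tree, k=config.cluster_k, k_max=config.cluster_k_max)
        result = rank_clusters(assignments, sets)
        (out / f"hub_{cls}.json").write_text(json.dumps(result.to_dict(), indent=1))
        _write_cluster_table(result, out / f"hub_{cls}.tsv")
        sel = result.selected()
        summary["hub"][cls] = {
            "n_clusters": len(result.clusters),
            "selected_cluster": result.selected_cluster,
            "a_genes": sel.a,
            "b_unique_carriers": sel.b,
            "ratio": sel.ratio,
            "coverage": sel.coverage,
        }
        stage(f"hub_{cls}", n_genes=len(genes), n_clusters=len(result.clusters))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def _write_gene_list(genes: list[str], path: Path) -> None:
    path.write_text("gene\n" + "".join(f"{g}\n" for g in genes))


def _write_cluster_table(result, path: Path) -> None:
    lines = ["cluster_id\ta_genes\tb_unique_carriers\tratio\tcoverage\tselected"]
    for c in result.clusters:
        lines.append(
            f"{c.cluster_id}\t{c.a}\t{c.b}\t{c.ratio:.6g}\t{c.coverage:.6g}\t"
            f"{int(c.cluster_id == result.selected_cluster)}"
        )
    path.write_text("\n".join(lines) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
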