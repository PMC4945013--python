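"""End-to-end orchestration: cluster, partition, contrast, report.

A single :class:`RunConfig` drives the full analysis flow on files the
readers understand: build the presence matrix, attach
multiscale-bootstrap support, extract the significant cluster around
the focal disorder, partition genes into roles, run the GERP / dN-dS /
pN-pS contrasts and the pathway analyses, and write a machine-readable
report bundle with a checksummed run manifest.

The config's single seed fans out to fixed per-stage seeds so each
stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io_tables import (
    read_association_table,
    read_bed,
    read_gene_stats,
    read_ko_mapping,
)
from .setops import build_presence_matrix, partition_by_cluster, unique_genes, write_partition
from .clustering import (
    DEFAULT_SCALES,
    multiscale_bootstrap,
    significant_clusters,
    to_newick,
)
from .constraint import compare_sets_mw, constrained_fraction, filter_elements
from .selection import compare_dnds, resampling_test, run_panel_contrasts
from .pathways import bipartite_degrees, map_genes_to_kos, pathway_coverage, unique_pathways

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "cognitive_contrast", "PipelineError"]

_STAGE_SEED = {"bootstrap": 11, "pnps": 23, "cognitive": 37}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs and parameters of a full pipeline run.

    Defaults mirror the analysis' reference settings: cluster
    significance level 0.15 on AU, constrained-element p-value threshold
    0.05, 1000 resamplings for both the multiscale bootstrap and the
    pN/pS null.
    """

    associations: str
    gene_stats: str
    genes_bed: str
    elements_bed: str
    focal: str
    out_dir: str
    seed: int
    ko_gene: str | None = None
    ko_pathway: str | None = None
    ko_pathway_size: str | None = None
    cluster_alpha: float = 0.15
    element_p_threshold: float = 0.05
    B: int = 1000
    n_boot: int = 1000
    scales: tuple[float, ...] = DEFAULT_SCALES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "scales" in raw:
            raw["scales"] = tuple(float(r) for r in raw["scales"])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return int((self.seed * 1000 + _STAGE_SEED[stage]) % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage; returns the report dict (also written to disk).

    Writes under ``cfg.out_dir``: dendrogram.nwk, cluster_diagnostics.tsv,
    fit_curves.tsv, partition.tsv, constrained_fractions.tsv,
    report.json and manifest.json.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"focal": cfg.focal, "seed": cfg.seed, "version": __version__}

    # --- load inputs -----------------------------------------------------
    stage = "load"
    try:
        assoc = read_association_table(cfg.associations)
        stats = read_gene_stats(cfg.gene_stats)
        genes_iv = read_bed(cfg.genes_bed)
        elements_iv = read_bed(cfg.elements_bed)
        komap = None
        if cfg.ko_gene and cfg.ko_pathway and cfg.ko_pathway_size:
            komap = read_ko_mapping(cfg.ko_gene, cfg.ko_pathway, cfg.ko_pathway_size)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- clustering ------------------------------------------------------
    stage = "clustering"
    try:
        matrix = build_presence_matrix(assoc)
        dendro = multiscale_bootstrap(
            matrix,
            n_boot=cfg.n_boot,
            scales=cfg.scales,
            seed=cfg.stage_seed("bootstrap"),
        )
        clusters = significant_clusters(dendro, alpha=cfg.cluster_alpha)
        (out / "dendrogram.nwk").write_text(to_newick(dendro) + "\n")
        dendro.diagnostics().to_csv(out / "cluster_diagnostics.tsv", sep="\t", index=False)
        dendro.fit_curves().to_csv(out / "fit_curves.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    focal_cluster = next((c for c in clusters if cfg.focal in c), None)
    if focal_cluster is None:
        logger.warning("no significant cluster contains %s; using focal alone", cfg.focal)
        focal_cluster = frozenset([cfg.focal])
    report["significant_clusters"] = [sorted(c) for c in clusters]
    report["focal_cluster"] = sorted(focal_cluster)

    # --- partition -------------------------------------------------------
    stage = "partition"
    try:
        partition = partition_by_cluster(matrix, cfg.focal, focal_cluster)
        write_partition(partition, matrix, out / "partition.tsv")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    focal_genes = partition.focal_genes
    report["counts"] = {
        "focal_genes": len(focal_genes),
        "focal_only": len(partition["focal_only"]),
        "focal_shared": len(focal_genes) - len(partition["focal_only"]),
        **{role: len(partition[role]) for role in partition.sets},
    }
    assert partition["focal_only"] == frozenset(unique_genes(matrix, cfg.focal))

    # --- GERP constrained-fraction contrast ------------------------------
    stage = "gerp"
    try:
        elements = filter_elements(elements_iv, cfg.element_p_threshold)
        profile = constrained_fraction(genes_iv, elements)
        profile.frame.to_csv(out / "constrained_fractions.tsv", sep="\t")
        frac_only = profile.fractions(partition["focal_only"])
        shared = focal_genes - partition["focal_only"]
        frac_shared = profile.fractions(shared)
        u, p = compare_sets_mw(frac_only, frac_shared)
        report["gerp"] = {
            "U": u,
            "p_value": p,
            "n_focal_only": int(len(frac_only)),
            "n_shared": int(len(frac_shared)),
            "median_focal_only": float(np.median(frac_only)),
            "median_shared": float(np.median(frac_shared)),
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- dN/dS contrast ---------------------------------------------------
    stage = "dnds"
    try:
        u, p = compare_dnds(partition["focal_only"], shared, stats)
        report["dnds"] = {"U": u, "p_value": p}
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- pN/pS panel contrasts --------------------------------------------
    stage = "pnps"
    try:
        panels = run_panel_contrasts(
            partition, stats, B=cfg.B, seed=cfg.stage_seed("pnps")
        )
        report["pnps"] = {r.label: r.summary() for r in panels}
        null_dump = {
            r.label: [float(x) for x in r.null_ratios] for r in panels
        }
        (out / "pnps_null_ratios.json").write_text(json.dumps(null_dump))
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- pathways ---------------------------------------------------------
    if komap is not None:
        stage = "pathways"
        try:
            focal_kos, unmapped = map_genes_to_kos(focal_genes, komap)
            coverage = pathway_coverage(focal_kos, komap)
            coverage.frame.to_csv(out / "pathway_coverage.tsv", sep="\t")
            other_sets = [
                map_genes_to_kos(matrix.genes_of(d), komap)[0]
                for d in matrix.disorders
                if d != cfg.focal
            ]
            uniq = unique_pathways(focal_kos, other_sets, komap)
            degrees = bipartite_degrees(focal_kos, komap)
            degrees.write_edge_list(out / "ko_pathway_edges.tsv")
            degrees.ko_degree.rename("degree").to_csv(out / "ko_degrees.tsv", sep="\t")
            report["pathways"] = {
                "n_mapped_kos": len(focal_kos),
                "n_unmapped_genes": len(unmapped),
                "n_pathways_hit": int(len(coverage.frame)),
                "unique_to_focal": sorted(uniq),
                "top_coverage": coverage.top(15).reset_index().to_dict("records"),
            }
        except Exception as exc:
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- report + manifest -------------------------------------------------
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    inputs = {
        name: {"path": str(p), "sha256": _sha256(Path(p))}
        for name, p in (
            ("associations", cfg.associations),
            ("gene_stats", cfg.gene_stats),
            ("genes_bed", cfg.genes_bed),
            ("elements_bed", cfg.elements_bed),
        )
    }
    outputs = {
        f.name: _sha256(f)
        for f in sorted(out.iterdir())
        if f.is_file() and f.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "inputs": inputs,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return report


def cognitive_contrast(cfg: RunConfig, cognitive_ids) -> dict:
    """Contrast cognitive-disorder genes against focal-only and the rest.

    Builds the union gene set of the given cognitive disorders
    (focal excluded) and of the remaining non-cognitive disorders, then
    runs the pN/pS resampling test and the dN/dS comparison on
    (focal-only vs cognitive) and (cognitive vs non-cognitive).
    """
    assoc = read_association_table(cfg.associations)
    stats = read_gene_stats(cfg.gene_stats)
    matrix = build_presence_matrix(assoc)
    cognitive = frozenset(cognitive_ids)
    unknown = cognitive - set(matrix.disorders)
    if unknown:
        raise ValueError(f"unknown cognitive disorder ids: {sorted(unknown)}")

    focal_only = frozenset(unique_genes(matrix, cfg.focal))
    cognitive_genes = frozenset().union(
        *(matrix.genes_of(d) for d in cognitive if d != cfg.focal)
    )
    non_cognitive = [
        d for d in matrix.disorders if d not in cognitive and d != cfg.focal
    ]
    non_cognitive_genes = (
        frozenset().union(*(matrix.genes_of(d) for d in non_cognitive))
        if non_cognitive
        else frozenset()
    )

    seed = cfg.stage_seed("cognitive")
    report: dict = {"cognitive_ids": sorted(cognitive), "seed": seed}

    small, large = sorted(
        (focal_only, cognitive_genes), key=len
    )
    res = resampling_test(
        small, large, stats, B=cfg.B, seed=seed, label="focal_only_vs_cognitive"
    )
    u, p = compare_dnds(focal_only, cognitive_genes, stats)
    report["focal_only_vs_cognitive"] = {
        "pnps": res.summary(),
        "dnds": {"U": u, "p_value": p},
    }

    if non_cognitive_genes:
        small, large = sorted(
            (cognitive_genes, non_cognitive_genes), key=len
        )
        res2 = resampling_test(
            small, large, stats, B=cfg.B, seed=seed + 1,
            label="cognitive_vs_non_cognitive",
        )
        u2, p2 = compare_dnds(cognitive_genes, non_cognitive_genes, stats)
        report["cognitive_vs_non_cognitive"] = {
            "pnps": res2.summary(),
            "dnds": {"U": u2, "p_value": p2},
        }
    else:
        logger.warning("no non-cognitive disorders; complement contrast skipped")
        report["cognitive_vs_non_cognitive"] = None
    return report
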