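"""Synthetic input generator with planted structure.

Emulates every input of the comorbidity pipeline so each stage is
testable offline: a disorder x gene association table with planted
disorder blocks (elevated within-block gene sharing), a planted
focal-only gene set, per-gene pN/pS counts with role-dependent
intensity omega = E[pN]/E[pS], per-gene dN/dS values with a role-shifted
lognormal, gene/constrained-element intervals with role-dependent
constrained-base density, and a sparse KO/pathway snapshot.

The generative model for polymorphism counts is deliberately simple:
pS ~ max(1, Poisson(length * rate)) and pN | pS ~ Poisson(omega * pS),
which makes the set-level mean(pN)/mean(pS) statistic a consistent
estimator of omega for a homogeneous set.  Everything is deterministic
given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_tables import (
    AssociationTable,
    GeneStatsTable,
    IntervalSet,
    KOMapping,
    make_interval_set,
    write_association_table,
    write_bed,
    write_gene_stats,
    write_ko_mapping,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "gen_association_matrix",
    "gen_gene_stats",
    "gen_intervals",
    "gen_ko_snapshot",
    "write_synthetic_inputs",
]

_ROLE_DEFAULT = "default"


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study, with planted-structure defaults.

    The defaults define the reference study conditions used throughout
    the test-bench: 6 disorders in two blocks of three, 400 genes,
    within/between-block sharing probabilities 0.8/0.05, a quarter of
    genes unique to the focal disorder, selection intensity omega 0.35
    for focal-only genes vs 0.25 for shared ones, and constrained-base
    densities 0.4 vs 0.6 in the opposite direction (shared genes more
    constrained).
    """

    seed: int
    n_disorders: int = 6
    n_genes: int = 400
    cluster_blocks: tuple[tuple[int, ...], ...] = ((0, 1, 2), (3, 4, 5))
    focal_index: int = 0
    within_block_share_prob: float = 0.8
    between_block_share_prob: float = 0.05
    focal_unique_frac: float = 0.25
    focal_shared_frac: float = 0.35
    omega_by_role: dict = field(
        default_factory=lambda: {"focal_only": 0.35, _ROLE_DEFAULT: 0.25}
    )
    ps_rate_per_base: float = 1.0 / 200.0
    gene_length_meanlog: float = float(np.log(1000.0))
    gene_length_sdlog: float = 0.5
    dnds_meanlog_by_role: dict = field(
        default_factory=lambda: {
            "focal_only": float(np.log(0.25)) + 0.4,
            _ROLE_DEFAULT: float(np.log(0.25)),
        }
    )
    dnds_sdlog: float = 0.5
    constrained_density_by_role: dict = field(
        default_factory=lambda: {"focal_only": 0.4, _ROLE_DEFAULT: 0.6}
    )
    constrained_density_noise: float = 0.05
    decoy_element_prob: float = 0.5
    ko_per_gene: int = 1
    n_kos: int = 150
    pathways_per_ko: int = 2
    n_pathways: int = 40
    pathway_extra_kos: float = 3.0

    def __post_init__(self) -> None:
        for name in (
            "within_block_share_prob",
            "between_block_share_prob",
            "focal_unique_frac",
            "focal_shared_frac",
            "decoy_element_prob",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.focal_unique_frac + self.focal_shared_frac > 1.0:
            raise ValueError("focal_unique_frac + focal_shared_frac exceeds 1")
        covered = sorted(i for blk in self.cluster_blocks for i in blk)
        if covered != list(range(self.n_disorders)):
            raise ValueError(
                "cluster_blocks must partition disorder indices "
                f"0..{self.n_disorders - 1}"
            )
        if any(w < 0 for w in self.omega_by_role.values()):
            raise ValueError("omega values must be non-negative")
        if any(not (0.0 <= d <= 1.0) for d in self.constrained_density_by_role.values()):
            raise ValueError("constrained densities must lie in [0, 1]")
        if self.focal_index not in covered:
            raise ValueError("focal_index out of range")

    def role_value(self, mapping: dict, role: str):
        return mapping.get(role, mapping[_ROLE_DEFAULT])


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    disorders: list[str]
    focal: str
    blocks: list[frozenset[str]]
    cluster: frozenset[str]  # the block containing the focal disorder
    genes: list[str]
    role_of: dict[str, str]
    gene_lengths: dict[str, int]
    omega_by_role: dict
    constrained_density_by_role: dict

    def genes_with_role(self, role: str) -> frozenset[str]:
        return frozenset(g for g, r in self.role_of.items() if r == role)

    def to_json(self) -> str:
        payload = {
            "disorders": self.disorders,
            "focal": self.focal,
            "blocks": [sorted(b) for b in self.blocks],
            "cluster": sorted(self.cluster),
            "genes": self.genes,
            "role_of": self.role_of,
            "gene_lengths": self.gene_lengths,
            "omega_by_role": self.omega_by_role,
            "constrained_density_by_role": self.constrained_density_by_role,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _rng(cfg: SimulationConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(stage,)))


def gen_association_matrix(
    cfg: SimulationConfig,
) -> tuple[AssociationTable, SyntheticTruth]:
    """Planted-block disorder x gene associations plus ground truth.

    Each gene is first drawn as focal-only, focal-shared or non-focal;
    shared genes are co-assigned to further disorders with probability
    ``within_block_share_prob`` inside their home block and
    ``between_block_share_prob`` outside, with at least one non-focal
    membership forced for shared genes.  The recorded truth role is the
    role realized by the final membership pattern relative to the
    planted cluster (the block containing the focal disorder), so exact
    recovery by the partition stage is well defined.
    """
    rng = _rng(cfg, 0)
    disorders = [f"D{i}" for i in range(cfg.n_disorders)]
    focal = disorders[cfg.focal_index]
    blocks = [frozenset(disorders[i] for i in blk) for blk in cfg.cluster_blocks]
    cluster = next(b for b in blocks if focal in b)
    block_of = {d: b for b in blocks for d in b}

    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    lengths = {
        g: int(
            max(
                90,
                round(rng.lognormal(cfg.gene_length_meanlog, cfg.gene_length_sdlog)),
            )
        )
        for g in genes
    }

    records: list[tuple[str, str]] = []
    role_of: dict[str, str] = {}
    others = [d for d in disorders if d != focal]
    for g in genes:
        u = rng.random()
        if u < cfg.focal_unique_frac:
            members = {focal}
        elif u < cfg.focal_unique_frac + cfg.focal_shared_frac:
            members = {focal}
            members |= _draw_members(
                rng, others, block_of[focal], block_of, cfg
            )
            if members == {focal}:
                pool = sorted(block_of[focal] - {focal}) or others
                members.add(pool[int(rng.integers(len(pool)))])
        else:
            home = blocks[int(rng.integers(len(blocks)))]
            candidates = [d for d in others]
            members = _draw_members(rng, candidates, home, block_of, cfg)
            if not members:
                pool = sorted(home - {focal}) or candidates
                members.add(pool[int(rng.integers(len(pool)))])
        for d in sorted(members):
            records.append((d, g))
        role_of[g] = _realized_role(members, focal, cluster)

    table = AssociationTable(records=records)
    truth = SyntheticTruth(
        disorders=disorders,
        focal=focal,
        blocks=blocks,
        cluster=cluster,
        genes=genes,
        role_of=role_of,
        gene_lengths=lengths,
        omega_by_role=dict(cfg.omega_by_role),
        constrained_density_by_role=dict(cfg.constrained_density_by_role),
    )
    return table, truth


def _draw_members(rng, candidates, home_block, block_of, cfg) -> set[str]:
    members = set()
    for d in candidates:
        p = (
            cfg.within_block_share_prob
            if d in home_block
            else cfg.between_block_share_prob
        )
        if rng.random() < p:
            members.add(d)
    return members


def _realized_role(members: set[str], focal: str, cluster: frozenset[str]) -> str:
    in_cluster_others = (members & cluster) - {focal}
    out_cluster = members - cluster
    if focal in members:
        if not in_cluster_others and not out_cluster:
            return "focal_only"
        if out_cluster:
            return "focal_shared_out_cluster"
        return "focal_shared_in_cluster"
    if in_cluster_others:
        return "cluster_non_focal"
    return "outside_cluster"


def gen_gene_stats(truth: SyntheticTruth, cfg: SimulationConfig) -> GeneStatsTable:
    """Per-gene pS, pN and dN/dS with role-dependent intensities."""
    rng = _rng(cfg, 1)
    rows = []
    for g in truth.genes:
        role = truth.role_of[g]
        omega = cfg.role_value(cfg.omega_by_role, role)
        ps = max(1, int(rng.poisson(truth.gene_lengths[g] * cfg.ps_rate_per_base)))
        pn = int(rng.poisson(omega * ps))
        meanlog = cfg.role_value(cfg.dnds_meanlog_by_role, role)
        dnds = float(rng.lognormal(meanlog, cfg.dnds_sdlog))
        rows.append((g, pn, ps, dnds))
    frame = pd.DataFrame(rows, columns=["gene", "pN", "pS", "dnds"]).set_index("gene")
    return GeneStatsTable(frame=frame.astype({"pN": float, "pS": float, "dnds": float}))


def gen_intervals(
    truth: SyntheticTruth, cfg: SimulationConfig
) -> tuple[IntervalSet, IntervalSet]:
    """Gene footprints and constrained elements on a synthetic contig.

    Genes are laid end-to-end (100 bp gaps) on contig ``chrS1``.  Each
    gene receives one significant element (p-value < 0.05) sized to hit
    its role's constrained density plus Gaussian placement noise, and,
    with probability ``decoy_element_prob``, one non-significant decoy
    element (p-value > 0.05) that the significance filter must remove.
    """
    rng = _rng(cfg, 2)
    gene_rows = []
    element_rows = []
    pos = 0
    for g in truth.genes:
        length = truth.gene_lengths[g]
        start, end = pos, pos + length
        gene_rows.append(("chrS1", start, end, g))
        role = truth.role_of[g]
        density = cfg.role_value(cfg.constrained_density_by_role, role)
        f = float(
            np.clip(rng.normal(density, cfg.constrained_density_noise), 0.0, 1.0)
        )
        elen = int(round(f * length))
        if elen > 0:
            offset = int(rng.integers(0, length - elen + 1))
            pval = float(rng.uniform(0.0, 0.049))
            element_rows.append(
                ("chrS1", start + offset, start + offset + elen, f"{g}_sig", pval)
            )
        if rng.random() < cfg.decoy_element_prob:
            dlen = int(rng.integers(10, max(11, length // 2)))
            offset = int(rng.integers(0, length - dlen + 1))
            pval = float(rng.uniform(0.051, 1.0))
            element_rows.append(
                ("chrS1", start + offset, start + offset + dlen, f"{g}_decoy", pval)
            )
        pos = end + 100
    return make_interval_set(gene_rows), make_interval_set(element_rows)


def gen_ko_snapshot(genes, cfg: SimulationConfig) -> KOMapping:
    """Sparse random gene->KO and KO->pathway snapshot.

    Every gene draws ``ko_per_gene`` distinct KOs from a pool of
    ``n_kos``; every pool KO belongs to ``pathways_per_ko`` distinct
    pathways.  Declared pathway sizes are the pool membership counts
    plus a Poisson number of unobserved extra KOs, so coverage is always
    a valid percentage.
    """
    rng = _rng(cfg, 3)
    kos = [f"K{i:05d}" for i in range(cfg.n_kos)]
    pathways = [f"path{i:04d}" for i in range(cfg.n_pathways)]
    ko_to_pathway = {
        ko: frozenset(
            pathways[j]
            for j in rng.choice(
                cfg.n_pathways, size=min(cfg.pathways_per_ko, cfg.n_pathways), replace=False
            )
        )
        for ko in kos
    }
    gene_to_ko = {}
    for g in sorted(set(genes)):
        k = min(cfg.ko_per_gene, cfg.n_kos)
        if k > 0:
            picks = rng.choice(cfg.n_kos, size=k, replace=False)
            gene_to_ko[g] = frozenset(kos[i] for i in picks)
    member_count: dict[str, int] = {p: 0 for p in pathways}
    for pws in ko_to_pathway.values():
        for p in pws:
            member_count[p] += 1
    pathway_size = {
        p: max(1, member_count[p]) + int(rng.poisson(cfg.pathway_extra_kos))
        for p in pathways
    }
    return KOMapping(
        gene_to_ko=gene_to_ko,
        ko_to_pathway=ko_to_pathway,
        pathway_size=pathway_size,
    )


def write_synthetic_inputs(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate the full input bundle and write it in reader formats.

    Returns the written paths.  Byte-identical output for identical
    config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assoc, truth = gen_association_matrix(cfg)
    stats = gen_gene_stats(truth, cfg)
    genes_iv, elements_iv = gen_intervals(truth, cfg)
    komap = gen_ko_snapshot(truth.genes, cfg)

    paths = {
        "associations": outdir / "associations.tsv",
        "gene_stats": outdir / "gene_stats.tsv",
        "genes_bed": outdir / "genes.bed",
        "elements_bed": outdir / "elements.bed",
        "truth": outdir / "truth.json",
    }
    write_association_table(assoc, paths["associations"])
    write_gene_stats(stats, paths["gene_stats"])
    write_bed(genes_iv, paths["genes_bed"])
    write_bed(elements_iv, paths["elements_bed"])
    paths.update(write_ko_mapping(komap, outdir / "ko_snapshot"))
    paths["truth"].write_text(truth.to_json() + "\n")
    return paths
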