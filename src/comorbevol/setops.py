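"""Disorder x gene presence/absence matrix and gene-set partitions.

The central objects of the comorbidity analysis: a binary membership
matrix over (disorder, gene) pairs, the set of genes unique to a focal
disorder, and the five-role partition of all genes relative to a focal
disorder and a cluster of comorbid disorders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_tables import AssociationTable

__all__ = [
    "PresenceMatrix",
    "GeneSetPartition",
    "ROLES",
    "build_presence_matrix",
    "unique_genes",
    "partition_by_cluster",
    "write_partition",
]

ROLES = (
    "focal_only",
    "focal_shared_in_cluster",
    "focal_shared_out_cluster",
    "cluster_non_focal",
    "outside_cluster",
)


@dataclass
class PresenceMatrix:
    """Binary disorder x gene membership matrix.

    ``values[i, j]`` is 1 iff gene ``genes[j]`` is associated with
    disorder ``disorders[i]``.  Labels are unique and every gene column
    has at least one nonzero cell (genes enter only via associations).
    """

    disorders: list[str]
    genes: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        n_d, n_g = self.values.shape
        if n_d != len(self.disorders) or n_g != len(self.genes):
            raise ValueError("matrix shape does not match labels")
        if len(set(self.disorders)) != n_d or len(set(self.genes)) != n_g:
            raise ValueError("duplicate row or column labels")
        if n_g and (self.values.sum(axis=0) == 0).any():
            raise ValueError("all-zero gene column")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, disorder: str) -> np.ndarray:
        return self.values[self._row_index(disorder)]

    def genes_of(self, disorder: str) -> set[str]:
        mask = self.row(disorder).astype(bool)
        return {g for g, m in zip(self.genes, mask) if m}

    def _row_index(self, disorder: str) -> int:
        try:
            return self.disorders.index(disorder)
        except ValueError:
            raise KeyError(f"unknown disorder {disorder!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.disorders, columns=self.genes)


@dataclass
class GeneSetPartition:
    """Named role sets of genes relative to a focal disorder and cluster.

    Roles: ``focal_only`` (genes of the focal disorder and no other),
    ``focal_shared_in_cluster`` / ``focal_shared_out_cluster`` (focal
    genes shared with comorbid disorders inside / outside the cluster),
    ``cluster_non_focal`` (non-focal genes of in-cluster disorders) and
    ``outside_cluster`` (genes only of out-of-cluster disorders).  Role
    sets are pairwise disjoint and the focal roles union to the focal
    disorder's gene set.
    """

    focal: str
    cluster_members: frozenset[str]
    sets: dict[str, frozenset[str]]
    shared_tie_rule: str = "out_cluster"

    def __post_init__(self) -> None:
        missing = set(ROLES) - set(self.sets)
        if missing:
            raise ValueError(f"partition missing roles: {sorted(missing)}")
        roles = list(self.sets)
        for i, a in enumerate(roles):
            for b in roles[i + 1 :]:
                overlap = self.sets[a] & self.sets[b]
                if overlap:
                    raise ValueError(
                        f"roles {a!r} and {b!r} overlap: {sorted(overlap)[:5]}"
                    )

    def __getitem__(self, role: str) -> frozenset[str]:
        return self.sets[role]

    @property
    def focal_genes(self) -> frozenset[str]:
        return (
            self.sets["focal_only"]
            | self.sets["focal_shared_in_cluster"]
            | self.sets["focal_shared_out_cluster"]
        )


def build_presence_matrix(assoc: AssociationTable) -> PresenceMatrix:
    """Binary presence/absence matrix from an association table.

    Disorders and genes are ordered lexicographically so the matrix is
    invariant to input record order.  Requires at least two disorders.
    """
    membership = assoc.membership()
    if len(membership) < 2:
        raise ValueError(
            f"need at least 2 disorders to build a presence matrix, got {len(membership)}"
        )
    disorders = sorted(membership)
    genes = sorted({g for s in membership.values() for g in s})
    gene_index = {g: j for j, g in enumerate(genes)}
    values = np.zeros((len(disorders), len(genes)), dtype=np.int8)
    for i, d in enumerate(disorders):
        for g in membership[d]:
            values[i, gene_index[g]] = 1
    return PresenceMatrix(disorders=disorders, genes=genes, values=values)


def unique_genes(matrix: PresenceMatrix, focal: str) -> set[str]:
    """Genes present in the focal disorder and absent from every other."""
    i = matrix._row_index(focal)
    others = np.delete(matrix.values, i, axis=0)
    mask = matrix.values[i].astype(bool) & ~others.any(axis=0)
    return {g for g, m in zip(matrix.genes, mask) if m}


def partition_by_cluster(
    matrix: PresenceMatrix,
    focal: str,
    cluster_members: Iterable[str],
    *,
    shared_tie_rule: str = "out_cluster",
) -> GeneSetPartition:
    """Partition all genes into the five roles for a focal disorder.

    ``shared_tie_rule`` resolves focal genes shared with BOTH in- and
    out-of-cluster disorders: ``"out_cluster"`` (default) assigns them to
    ``focal_shared_out_cluster``, ``"in_cluster"`` to
    ``focal_shared_in_cluster``.
    """
    cluster = frozenset(cluster_members)
    if focal not in cluster:
        raise ValueError(f"focal disorder {focal!r} must be a cluster member")
    unknown = cluster - set(matrix.disorders)
    if unknown:
        raise ValueError(f"cluster members not in matrix: {sorted(unknown)}")
    if shared_tie_rule not in ("out_cluster", "in_cluster"):
        raise ValueError(f"unknown shared_tie_rule {shared_tie_rule!r}")

    vals = matrix.values.astype(bool)
    focal_row = vals[matrix._row_index(focal)]
    in_cluster_idx = [
        i for i, d in enumerate(matrix.disorders) if d in cluster and d != focal
    ]
    out_cluster_idx = [
        i for i, d in enumerate(matrix.disorders) if d not in cluster
    ]
    in_any = vals[in_cluster_idx].any(axis=0) if in_cluster_idx else np.zeros_like(focal_row)
    out_any = vals[out_cluster_idx].any(axis=0) if out_cluster_idx else np.zeros_like(focal_row)

    focal_only = focal_row & ~in_any & ~out_any
    if shared_tie_rule == "out_cluster":
        shared_out = focal_row & out_any
        shared_in = focal_row & in_any & ~out_any
    else:
        shared_in = focal_row & in_any
        shared_out = focal_row & out_any & ~in_any
    cluster_non_focal = ~focal_row & in_any
    outside = ~focal_row & ~in_any & out_any

    genes = np.asarray(matrix.genes)
    sets = {
        "focal_only": frozenset(genes[focal_only]),
        "focal_shared_in_cluster": frozenset(genes[shared_in]),
        "focal_shared_out_cluster": frozenset(genes[shared_out]),
        "cluster_non_focal": frozenset(genes[cluster_non_focal]),
        "outside_cluster": frozenset(genes[outside]),
    }
    return GeneSetPartition(
        focal=focal,
        cluster_members=cluster,
        sets=sets,
        shared_tie_rule=shared_tie_rule,
    )


def write_partition(
    partition: GeneSetPartition, matrix: PresenceMatrix, path: str | Path
) -> None:
    """Write the partition as TSV: gene, role, defining disorders."""
    vals = matrix.values.astype(bool)
    gene_index = {g: j for j, g in enumerate(matrix.genes)}
    rows = []
    for role in ROLES:
        for gene in sorted(partition.sets[role]):
            j = gene_index[gene]
            defining = ",".join(
                d for d, present in zip(matrix.disorders, vals[:, j]) if present
            )
            rows.append((gene, role, defining))
    pd.DataFrame(rows, columns=["gene", "role", "disorders"]).to_csv(
        path, sep="\t", index=False
    )
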