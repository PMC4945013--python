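"""Pathway coverage and KO-pathway bipartite degree analysis.

Gene symbols are mapped to KEGG Orthologs (KOs) through an offline
snapshot, KOs onto pathways, and each touched pathway is scored by
coverage: the percentage of its total KOs hit by the gene set.
Pathways unique to a focal disorder are those touched by the focal KO
set and by no other disorder's.  The KO-pathway incidence is also
summarized as a bipartite graph with per-node degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .io_tables import KOMapping

__all__ = [
    "PathwayCoverage",
    "BipartiteDegreeReport",
    "map_genes_to_kos",
    "pathway_coverage",
    "unique_pathways",
    "bipartite_degrees",
]


@dataclass
class PathwayCoverage:
    """Coverage of each pathway touched by a KO set.

    ``frame`` is indexed by pathway id with columns ``n_hit``,
    ``total_kos`` and ``coverage_pct`` (0-100), sorted by descending
    coverage then pathway id.  ``hit_kos`` maps pathway -> KOs hit.
    """

    frame: pd.DataFrame
    hit_kos: dict[str, frozenset[str]]

    def top(self, k: int = 15) -> pd.DataFrame:
        return self.frame.head(k)

    @property
    def pathways(self) -> set[str]:
        return set(self.frame.index)


@dataclass
class BipartiteDegreeReport:
    """Degrees on the KO-pathway bipartite incidence graph."""

    ko_degree: pd.Series  # per KO: number of pathways containing it
    pathway_degree: pd.Series  # per pathway: number of KOs hitting it
    edges: list[tuple[str, str]]  # (ko, pathway)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ko_degree.index, bipartite="ko")
        g.add_nodes_from(self.pathway_degree.index, bipartite="pathway")
        g.add_edges_from(self.edges)
        return g

    def ranked_kos(self) -> pd.Series:
        return self.ko_degree

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("ko\tpathway\n")
            for ko, pw in sorted(self.edges):
                fh.write(f"{ko}\t{pw}\n")


def map_genes_to_kos(genes, komap: KOMapping) -> tuple[frozenset[str], list[str]]:
    """Union of KO sets over mapped genes, plus the unmapped genes."""
    kos: set[str] = set()
    unmapped = []
    for gene in sorted(set(genes)):
        hit = komap.gene_to_ko.get(gene)
        if hit:
            kos |= hit
        else:
            unmapped.append(gene)
    return frozenset(kos), unmapped


def pathway_coverage(kos, komap: KOMapping) -> PathwayCoverage:
    """Coverage per pathway touched by at least one KO.

    coverage_pct = 100 * |hit KOs| / total KOs of the pathway, using the
    snapshot's pathway sizes.  Sorted by descending coverage with
    pathway id as the deterministic tie-break.
    """
    hits: dict[str, set[str]] = {}
    for ko in sorted(set(kos)):
        for pw in komap.ko_to_pathway.get(ko, ()):  # KOs outside the snapshot map nowhere
            hits.setdefault(pw, set()).add(ko)
    rows = []
    for pw, hit in hits.items():
        total = komap.pathway_size[pw]
        if len(hit) > total:
            raise ValueError(
                f"pathway {pw!r}: {len(hit)} hit KOs exceed declared total {total}"
            )
        rows.append((pw, len(hit), total, 100.0 * len(hit) / total))
    frame = pd.DataFrame(
        rows, columns=["pathway", "n_hit", "total_kos", "coverage_pct"]
    ).set_index("pathway")
    frame = frame.sort_values(
        ["coverage_pct", "pathway"], ascending=[False, True], kind="mergesort"
    )
    return PathwayCoverage(frame=frame, hit_kos={p: frozenset(s) for p, s in hits.items()})


def unique_pathways(focal_kos, other_disorder_kos, komap: KOMapping) -> set[str]:
    """Pathways hit by the focal KO set and by no other disorder's KOs."""
    focal = pathway_coverage(focal_kos, komap).pathways
    others: set[str] = set()
    for kos in other_disorder_kos:
        others |= pathway_coverage(kos, komap).pathways
    unique = focal - others
    assert not (unique & others)
    return unique


def bipartite_degrees(kos, komap: KOMapping) -> BipartiteDegreeReport:
    """Degree report for the KO-pathway incidence restricted to a KO set.

    KO degree = number of snapshot pathways containing the KO; pathway
    degree = number of the given KOs hitting it.  Rankings are sorted by
    descending degree with id as the deterministic tie-break.  The
    handshake identity (sum of KO degrees = sum of pathway degrees =
    number of edges) holds by construction.
    """
    edges = sorted(
        (ko, pw)
        for ko in set(kos)
        for pw in komap.ko_to_pathway.get(ko, ())
    )
    ko_deg: dict[str, int] = {ko: 0 for ko in kos}
    pw_deg: dict[str, int] = {}
    for ko, pw in edges:
        ko_deg[ko] = ko_deg.get(ko, 0) + 1
        pw_deg[pw] = pw_deg.get(pw, 0) + 1
    ko_series = pd.Series(ko_deg, dtype=int).sort_index()
    ko_series = ko_series.sort_values(ascending=False, kind="mergesort")
    pw_series = pd.Series(pw_deg, dtype=int).sort_index()
    pw_series = pw_series.sort_values(ascending=False, kind="mergesort")
    assert int(ko_series.sum()) == int(pw_series.sum()) == len(edges)
    return BipartiteDegreeReport(
        ko_degree=ko_series, pathway_degree=pw_series, edges=edges
    )
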