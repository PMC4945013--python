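"""Validated readers and writers for the tabular and interval inputs.

All inputs are offline snapshot files: gene-disorder association tables,
per-gene polymorphism/divergence statistics, BED-like interval files
(gene footprints and constrained elements), KEGG-ortholog mapping
snapshots, and the ICD-9/MeSH disorder vocabulary.  Nothing here touches
the network.

Coordinate convention for intervals is BED: 0-based, half-open
``[start, end)``.  Gene symbols are normalized to uppercase with
surrounding whitespace stripped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationTable",
    "GeneStatsTable",
    "IntervalSet",
    "KOMapping",
    "FormatError",
    "ValidationError",
    "normalize_symbol",
    "read_association_table",
    "write_association_table",
    "read_vocabulary",
    "read_gene_stats",
    "write_gene_stats",
    "read_bed",
    "write_bed",
    "read_ko_mapping",
    "write_ko_mapping",
]


class FormatError(ValueError):
    """A file does not have the expected columns/shape."""


class ValidationError(ValueError):
    """A file parsed but its content violates an invariant."""


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: uppercase, whitespace-trimmed."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Association table


@dataclass
class AssociationTable:
    """Disorder -> gene membership records with optional vocabulary.

    ``records`` holds unique ``(disorder_id, gene)`` pairs after symbol
    normalization; ``vocabulary`` optionally maps a disorder id to its
    ICD-9 codes and MeSH term.
    """

    records: list[tuple[str, str]]
    vocabulary: dict[str, tuple[tuple[str, ...], str]] | None = None

    def __post_init__(self) -> None:
        if len(set(self.records)) != len(self.records):
            raise ValidationError("duplicate (disorder, gene) records")

    @property
    def disorders(self) -> list[str]:
        return sorted({d for d, _ in self.records})

    @property
    def genes(self) -> list[str]:
        return sorted({g for _, g in self.records})

    def genes_of(self, disorder: str) -> set[str]:
        return {g for d, g in self.records if d == disorder}

    def membership(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for d, g in self.records:
            out.setdefault(d, set()).add(g)
        return out


def read_association_table(
    path: str | Path,
    *,
    disorder_col: str = "disorder",
    gene_col: str = "gene",
) -> AssociationTable:
    """Read a TSV of (disorder, gene) associations.

    Duplicate pairs (after symbol normalization) are dropped with a
    logged count.  The two columns may be renamed via ``disorder_col`` /
    ``gene_col`` to accommodate supplementary-table dialects.
    """
    df = _read_tsv(path)
    for col in (disorder_col, gene_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    pairs = [
        (str(d).strip(), normalize_symbol(g))
        for d, g in zip(df[disorder_col], df[gene_col])
        if str(g).strip()
    ]
    unique = list(dict.fromkeys(pairs))
    n_dup = len(pairs) - len(unique)
    if n_dup:
        logger.info("read_association_table: dropped %d duplicate pairs", n_dup)
    return AssociationTable(records=unique)


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    df = pd.DataFrame(sorted(table.records), columns=["disorder", "gene"])
    df.to_csv(path, sep="\t", index=False)


def read_vocabulary(path: str | Path) -> dict[str, tuple[tuple[str, ...], str]]:
    """Read the ICD-9 / disorder / MeSH correspondence table.

    Expected columns: ``icd9`` (one code per row), ``disorder``,
    ``mesh``.  Multiple ICD-9 codes consolidating to one disorder appear
    as multiple rows; the reader groups them and makes no assumption
    about the number of distinct disorders.
    """
    df = _read_tsv(path)
    for col in ("icd9", "disorder", "mesh"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    vocab: dict[str, tuple[tuple[str, ...], str]] = {}
    for disorder, grp in df.groupby("disorder", sort=True):
        mesh = sorted(set(grp["mesh"].astype(str)))
        if len(mesh) > 1:
            raise ValidationError(
                f"{path}: disorder {disorder!r} maps to multiple MeSH terms {mesh}"
            )
        codes = tuple(sorted(set(grp["icd9"].astype(str))))
        vocab[str(disorder)] = (codes, mesh[0])
    return vocab


# ---------------------------------------------------------------------------
# Gene statistics


@dataclass
class GeneStatsTable:
    """Per-gene pN, pS polymorphism counts plus optional dN/dS and lengths.

    ``frame`` is indexed by normalized gene symbol with columns ``pN``,
    ``pS`` (non-negative counts), ``dnds`` (non-negative, NaN when
    missing), ``constrained_len`` and ``total_len`` (bases, NaN when
    missing).  Missing values are explicit NaN, never silent zeros.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            dups = f.index[f.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene keys: {dups[:5]}")
        for col in ("pN", "pS"):
            if col not in f.columns:
                raise FormatError(f"gene stats missing column {col!r}")
            if (f[col].dropna() < 0).any():
                raise ValidationError(f"negative values in column {col!r}")
        if "dnds" in f.columns and (f["dnds"].dropna() < 0).any():
            raise ValidationError("negative dN/dS values")
        if {"constrained_len", "total_len"} <= set(f.columns):
            both = f[["constrained_len", "total_len"]].dropna()
            if (both["constrained_len"] > both["total_len"]).any():
                raise ValidationError("constrained_len exceeds total_len")

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    def subset(self, genes: Iterable[str]) -> pd.DataFrame:
        """Rows for the given genes; silently drops genes absent from the table."""
        idx = self.frame.index.intersection(list(genes))
        return self.frame.loc[idx]


_STATS_NUMERIC = ["pN", "pS", "dnds", "constrained_len", "total_len"]


def read_gene_stats(path: str | Path) -> GeneStatsTable:
    """Read the per-gene statistics TSV (gene, pN, pS[, dnds, lengths])."""
    df = _read_tsv(path)
    for col in ("gene", "pN", "pS"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    df = df.copy()
    df["gene"] = df["gene"].map(normalize_symbol)
    for col in _STATS_NUMERIC:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{path}: unparseable {col!r} value {df[col].iloc[row]!r} "
                f"at data row {row + 1}"
            )
        df[col] = parsed
    keep = [c for c in _STATS_NUMERIC if c in df.columns]
    return GeneStatsTable(frame=df.set_index("gene")[keep])


def write_gene_stats(stats: GeneStatsTable, path: str | Path) -> None:
    stats.frame.sort_index().to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Intervals (BED-like)


@dataclass
class IntervalSet:
    """Sorted genomic intervals, 0-based half-open.

    ``frame`` columns: ``seq_id``, ``start``, ``end``, ``name`` (may be
    empty), ``pvalue`` (NaN when absent).  Sorted by (seq_id, start, end).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if (f["start"] >= f["end"]).any():
            bad = f[f["start"] >= f["end"]].iloc[0]
            raise ValidationError(
                f"interval with start >= end: {bad['seq_id']}:{bad['start']}-{bad['end']}"
            )
        pv = f["pvalue"].dropna()
        if ((pv < 0) | (pv > 1)).any():
            raise ValidationError("interval p-values must lie in [0, 1]")
        self.frame = (
            f.sort_values(["seq_id", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_pvalues(self) -> bool:
        return bool(self.frame["pvalue"].notna().all()) and len(self.frame) > 0

    def total_length(self) -> int:
        return int((self.frame["end"] - self.frame["start"]).sum())


def make_interval_set(
    rows: Iterable[tuple],
) -> IntervalSet:
    """Build an IntervalSet from (seq_id, start, end[, name[, pvalue]]) tuples."""
    recs = []
    for row in rows:
        seq_id, start, end = row[0], int(row[1]), int(row[2])
        name = str(row[3]) if len(row) > 3 and row[3] is not None else ""
        pvalue = float(row[4]) if len(row) > 4 and row[4] is not None else np.nan
        recs.append((str(seq_id), start, end, name, pvalue))
    df = pd.DataFrame(recs, columns=["seq_id", "start", "end", "name", "pvalue"])
    if df.empty:
        df = pd.DataFrame(
            {
                "seq_id": pd.Series(dtype=str),
                "start": pd.Series(dtype=np.int64),
                "end": pd.Series(dtype=np.int64),
                "name": pd.Series(dtype=str),
                "pvalue": pd.Series(dtype=float),
            }
        )
    return IntervalSet(frame=df)


def read_bed(path: str | Path) -> IntervalSet:
    """Read a 3-6 column BED-like file.

    Columns: seq, start, end, [name], [score].  The score column, when
    present, is interpreted as the element p-value (constrained-element
    files carry significance there).  Lines starting with ``#``,
    ``track`` or ``browser`` are skipped.
    """
    rows: list[tuple] = []
    for lineno, line in enumerate(_open_lines(path), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
        seq_id = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValidationError(
                f"{path}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
            ) from exc
        if start >= end:
            raise ValidationError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        name = fields[3] if len(fields) > 3 else ""
        pvalue = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                pvalue = float(fields[4])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: unparseable score/p-value {fields[4]!r}"
                ) from exc
        rows.append((seq_id, start, end, name, pvalue))
    if not rows:
        raise FormatError(f"{path}: empty interval file")
    return make_interval_set(rows)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for row in intervals.frame.itertuples(index=False):
            fields = [str(row.seq_id), str(int(row.start)), str(int(row.end))]
            if row.name or not np.isnan(row.pvalue):
                fields.append(row.name or ".")
            if not np.isnan(row.pvalue):
                fields.append(repr(float(row.pvalue)))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# KEGG-ortholog mapping snapshot


@dataclass
class KOMapping:
    """Offline snapshot of gene->KO and KO->pathway maps with pathway sizes."""

    gene_to_ko: dict[str, frozenset[str]]
    ko_to_pathway: dict[str, frozenset[str]]
    pathway_size: dict[str, int]

    def __post_init__(self) -> None:
        referenced = set().union(*self.ko_to_pathway.values()) if self.ko_to_pathway else set()
        missing = referenced - set(self.pathway_size)
        if missing:
            raise ValidationError(
                f"pathways without a size entry: {sorted(missing)[:5]}"
            )
        for pw, size in self.pathway_size.items():
            if size <= 0:
                raise ValidationError(f"pathway {pw!r} has non-positive total KO count")
        if any(not ko for ko in self.ko_to_pathway):
            raise ValidationError("empty KO id")


def read_ko_mapping(
    gene_ko_path: str | Path,
    ko_pathway_path: str | Path,
    pathway_size_path: str | Path,
) -> KOMapping:
    """Load the three snapshot TSVs: gene<->KO, KO<->pathway, pathway sizes."""
    gk = _read_tsv(gene_ko_path)
    kp = _read_tsv(ko_pathway_path)
    ps = _read_tsv(pathway_size_path)
    for df, cols, path in (
        (gk, ("gene", "ko"), gene_ko_path),
        (kp, ("ko", "pathway"), ko_pathway_path),
        (ps, ("pathway", "total_kos"), pathway_size_path),
    ):
        for col in cols:
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
    gene_to_ko: dict[str, set[str]] = {}
    for g, k in zip(gk["gene"], gk["ko"]):
        gene_to_ko.setdefault(normalize_symbol(g), set()).add(str(k))
    ko_to_pathway: dict[str, set[str]] = {}
    for k, p in zip(kp["ko"], kp["pathway"]):
        ko_to_pathway.setdefault(str(k), set()).add(str(p))
    pathway_size = {
        str(p): int(n) for p, n in zip(ps["pathway"], ps["total_kos"])
    }
    return KOMapping(
        gene_to_ko={g: frozenset(s) for g, s in gene_to_ko.items()},
        ko_to_pathway={k: frozenset(s) for k, s in ko_to_pathway.items()},
        pathway_size=pathway_size,
    )


def write_ko_mapping(komap: KOMapping, directory: str | Path) -> dict[str, Path]:
    """Write the snapshot as three TSVs under ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gene_ko": directory / "gene_ko.tsv",
        "ko_pathway": directory / "ko_pathway.tsv",
        "pathway_size": directory / "pathway_size.tsv",
    }
    pd.DataFrame(
        sorted((g, k) for g, kos in komap.gene_to_ko.items() for k in kos),
        columns=["gene", "ko"],
    ).to_csv(paths["gene_ko"], sep="\t", index=False)
    pd.DataFrame(
        sorted((k, p) for k, pws in komap.ko_to_pathway.items() for p in pws),
        columns=["ko", "pathway"],
    ).to_csv(paths["ko_pathway"], sep="\t", index=False)
    pd.DataFrame(
        sorted(komap.pathway_size.items()), columns=["pathway", "total_kos"]
    ).to_csv(paths["pathway_size"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# helpers


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty input file") from exc
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty input file")
    return df


def _open_lines(path: str | Path):
    import gzip

    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            yield from fh
    else:
        with open(path) as fh:
            yield from fh
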