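"""Expression profiling: representative set, CPM, average ribosome density.

Average ribosome density (ARD; also called translation efficiency) is the
per-gene ratio of CPM-normalized ribo-seq footprint counts to CPM-normalized
RNA-seq fragment counts.  Genes are ranked by RNA-seq fragments per nt of
coding sequence, the top fraction (default one third) forms the
representative set, and representative genes are rank-ordered by ARD into
octiles (octile 1 = highest ARD).

Normalization detail: the counts-per-million scale factor is computed from
the representative genes only, then applied to every gene, so CPM over the
representative set sums to exactly 1e6.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import GeneAnnotation
from .stats_core import spearman

__all__ = [
    "CountsTable",
    "ExpressionError",
    "read_counts_table",
    "write_counts_table",
    "combine_replicates",
    "select_representative_set",
    "normalize_cpm",
    "compute_ard",
    "assign_octiles",
    "synthesis_rates",
    "replicate_spearman",
    "build_expression_table",
]


class ExpressionError(ValueError):
    pass


@dataclass
class CountsTable:
    """Per-gene integer counts for one assay across one or more replicates."""

    assay: str  # "rna" or "ribo"
    counts: pd.DataFrame  # index: gene_id, columns: sample ids

    def __post_init__(self) -> None:
        if self.assay not in ("rna", "ribo"):
            raise ExpressionError(f"unknown assay {self.assay!r}")
        if self.counts.shape[1] < 1:
            raise ExpressionError("need at least one replicate column")
        if (self.counts.values < 0).any():
            raise ExpressionError("negative counts")
        if self.counts.index.has_duplicates:
            raise ExpressionError("duplicate gene ids")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def replicates(self) -> list[str]:
        return list(self.counts.columns)


def read_counts_table(path: str | Path, assay: str) -> CountsTable:
    """Read a counts TSV (first column gene_id; header may start with '#')."""
    with open(path) as fh:
        header = fh.readline().lstrip("#").strip().split("\t")
    df = pd.read_csv(path, sep="\t", skiprows=1, names=header, index_col=0)
    return CountsTable(assay=assay, counts=df.astype(np.int64))


def write_counts_table(path: str | Path, table: CountsTable) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\t" + "\t".join(map(str, table.replicates)) + "\n")
        table.counts.to_csv(fh, sep="\t", header=False)


def combine_replicates(tables: Sequence[CountsTable]) -> CountsTable:
    """Sum per-gene counts over all replicates of all given tables."""
    if not tables:
        raise ExpressionError("no tables given")
    assay = tables[0].assay
    genes = tables[0].counts.index
    total = pd.Series(0, index=genes, dtype=np.int64)
    for t in tables:
        if t.assay != assay:
            raise ExpressionError(f"assay mismatch: {t.assay!r} vs {assay!r}")
        if set(t.counts.index) != set(genes):
            raise ExpressionError("gene universe mismatch between replicates")
        total = total + t.counts.reindex(genes).sum(axis=1)
    return CountsTable(assay=assay, counts=total.to_frame("combined"))


def _lengths(genes: Iterable[GeneAnnotation] | Mapping[str, int]) -> pd.Series:
    if isinstance(genes, Mapping):
        return pd.Series(genes, dtype=float)
    return pd.Series({g.gene_id: g.length for g in genes}, dtype=float)


def select_representative_set(
    rna: CountsTable,
    genes: Iterable[GeneAnnotation] | Mapping[str, int],
    fraction: float = 1.0 / 3.0,
) -> list[str]:
    """Top ``floor(fraction * n)`` genes by RNA-seq count density (count/nt).

    Counts are replicate-summed before ranking.  Zero-density genes are
    excluded from the ranking; ties at the cut are broken by gene_id
    (lexicographically smaller kept), making the selection stable.
    """
    if not 0 < fraction <= 1:
        raise ExpressionError("fraction must be in (0, 1]")
    lengths = _lengths(genes)
    counts = rna.counts.sum(axis=1)
    missing = set(counts.index) - set(lengths.index)
    if missing:
        raise ExpressionError(f"no length for genes: {sorted(missing)[:5]} ...")
    density = counts / lengths.reindex(counts.index)
    n_target = int(np.floor(fraction * len(counts)))
    ranked = (
        density[density > 0]
        .to_frame("density")
        .reset_index(names="gene_id")
        .sort_values(["density", "gene_id"], ascending=[False, True])
    )
    return ranked["gene_id"].head(n_target).tolist()


def normalize_cpm(table: CountsTable, representative: Sequence[str]) -> pd.Series:
    """Counts per million, with the million taken over the representative set.

    cpm(g) = count(g) * 1e6 / sum of counts over representative genes.  A cpm
    is returned for every gene, inside the representative set or not.
    """
    if len(representative) == 0:
        raise ExpressionError("empty representative set")
    counts = table.counts.sum(axis=1).astype(float)
    total = counts.reindex(representative).sum()
    if not total > 0:
        raise ExpressionError("representative set has zero total counts")
    return counts * 1e6 / total


def compute_ard(rna_cpm: pd.Series, ribo_cpm: pd.Series) -> pd.Series:
    """ARD = ribo_cpm / rna_cpm; NaN (undefined) where rna_cpm == 0."""
    if set(rna_cpm.index) != set(ribo_cpm.index):
        raise ExpressionError("rna and ribo cpm cover different genes")
    ribo = ribo_cpm.reindex(rna_cpm.index)
    with np.errstate(divide="ignore", invalid="ignore"):
        ard = ribo / rna_cpm
    ard[rna_cpm == 0] = np.nan
    return ard


def assign_octiles(
    ard: pd.Series, representative: Sequence[str], n_octiles: int = 8
) -> pd.Series:
    """Rank representative genes by ARD (descending) into equal-size groups.

    Group size is floor(n / n_octiles); remainder genes (lowest ARD) are left
    unassigned.  Octile 1 holds the highest-ARD genes.  Ties are broken by
    gene_id for reproducibility.
    """
    vals = ard.reindex(representative)
    if vals.isna().any():
        bad = vals.index[vals.isna()].tolist()
        raise ExpressionError(f"undefined ARD for representative genes: {bad[:5]}")
    n = len(vals)
    if n < n_octiles:
        raise ExpressionError(f"need at least {n_octiles} genes, got {n}")
    size = n // n_octiles
    ordered = (
        vals.to_frame("ard")
        .reset_index(names="gene_id")
        .sort_values(["ard", "gene_id"], ascending=[False, True])
    )
    assigned = ordered.head(size * n_octiles)
    octiles = pd.Series(
        np.repeat(np.arange(1, n_octiles + 1), size),
        index=assigned["gene_id"].values,
        name="octile",
    )
    return octiles


def synthesis_rates(
    ribo: CountsTable, genes: Iterable[GeneAnnotation] | Mapping[str, int]
) -> pd.Series:
    """Relative protein synthesis rates: ribo coverage per nt, summing to 1e6."""
    lengths = _lengths(genes)
    counts = ribo.counts.sum(axis=1).astype(float)
    per_nt = counts / lengths.reindex(counts.index)
    total = per_nt.sum()
    if not total > 0:
        raise ExpressionError("no ribo-seq signal")
    return per_nt * 1e6 / total


def replicate_spearman(tables: Sequence[CountsTable] | CountsTable) -> pd.DataFrame:
    """Pairwise Spearman correlation of per-gene counts between replicates."""
    if isinstance(tables, CountsTable):
        df = tables.counts
    else:
        frames = [t.counts for t in tables]
        df = pd.concat(frames, axis=1)
    if df.shape[1] < 2:
        raise ExpressionError("need at least two replicates")
    cols = list(df.columns)
    out = pd.DataFrame(np.nan, index=cols, columns=cols, dtype=float)
    for a, b in itertools.combinations(cols, 2):
        r = spearman(df[a].values, df[b].values)
        out.loc[a, b] = r
        out.loc[b, a] = r
    np.fill_diagonal(out.values, 1.0)
    return out


def build_expression_table(
    rna_tables: Sequence[CountsTable],
    ribo_tables: Sequence[CountsTable],
    genes: Iterable[GeneAnnotation] | Mapping[str, int],
    fraction: float = 1.0 / 3.0,
    n_octiles: int = 8,
) -> pd.DataFrame:
    """Full per-gene expression report.

    Columns: rna_count, ribo_count (replicate-summed), rna_cpm, ribo_cpm,
    ard (NaN where undefined), synthesis_rate, representative (bool), octile
    (NaN if unassigned).
    """
    rna = combine_replicates(rna_tables)
    ribo = combine_replicates(ribo_tables)
    if set(rna.genes) != set(ribo.genes):
        raise ExpressionError("rna and ribo tables cover different genes")
    representative = select_representative_set(rna, genes, fraction)
    rna_cpm = normalize_cpm(rna, representative)
    ribo_cpm = normalize_cpm(ribo, representative).reindex(rna_cpm.index)
    ard = compute_ard(rna_cpm, ribo_cpm)
    octiles = assign_octiles(ard, representative, n_octiles)
    rates = synthesis_rates(ribo, genes)
    table = pd.DataFrame(
        {
            "rna_count": rna.counts["combined"],
            "ribo_count": ribo.counts["combined"],
            "rna_cpm": rna_cpm,
            "ribo_cpm": ribo_cpm,
            "ard": ard,
            "synthesis_rate": rates,
        }
    )
    table["representative"] = table.index.isin(representative)
    table["octile"] = octiles.reindex(table.index)
    return table
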