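"""Composition-matched AUG-underrepresentation statistics.

AUG trinucleotides other than the start codon could trigger spurious
initiation in organisms that lack Shine-Dalgarno elements.  The statistic
counts AUG occurrences near the start codon and normalizes them against the
same-composition trinucleotides GAU, GUA, AGU counted in the same windows,
with matched windows at the gene midpoint as a control.

Window definitions (mRNA offsets relative to the first base of the start
codon): tir_upstream = -21..-1, tir_downstream = +4..+24 (the start codon
itself is never counted), and two 20-nt midgene windows immediately 5'/3'
of the gene midpoint m = floor(length/2): [m-20, m) and [m, m+20).
Occurrences are counted at every start offset, overlapping allowed; counts
are summed across genes and one ratio per genome is formed from the
aggregate counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import GeneAnnotation, GenomeRecord, extract_tir_window
from .stats_core import ZeroVarianceError, bonferroni, one_sample_t, two_sample_t

TARGET = "AUG"
NORMALIZERS = ("GAU", "GUA", "AGU")
WINDOW_NAMES = (
    "tir_upstream",
    "tir_downstream",
    "midgene_upstream",
    "midgene_downstream",
)
MIN_MIDGENE_LENGTH = 43  # genes shorter than this cannot host both midgene windows

__all__ = [
    "TrinucleotideRatios",
    "count_trinucleotides_in_window",
    "gene_window_sequences",
    "genome_ratios",
    "ratios_table",
    "phylum_analysis",
]


@dataclass
class TrinucleotideRatios:
    """Aggregate AUG vs composition-matched counts for one genome."""

    genome_id: str
    counts: dict  # window -> {trinucleotide -> int}
    n_genes: int
    n_genes_midgene: int

    def ratio(self, window: str, normalizer: str) -> float:
        c = self.counts[window]
        if c[normalizer] == 0:
            return np.nan
        return c[TARGET] / c[normalizer]


def count_trinucleotides_in_window(window_seq: str, tri: str) -> int:
    """Occurrences of a trinucleotide at every offset (overlaps counted)."""
    if len(window_seq) < 3:
        raise ValueError("window shorter than 3 nt")
    if len(tri) != 3:
        raise ValueError("need a trinucleotide")
    return sum(
        1
        for i in range(len(window_seq) - 2)
        if window_seq[i : i + 3] == tri
    )


def gene_window_sequences(
    genomes: Mapping[str, GenomeRecord], gene: GeneAnnotation
) -> dict[str, str | None]:
    """The four window sequences for one gene, in mRNA sense (RNA alphabet).

    Midgene windows are None for genes shorter than 43 nt; TIR windows are
    returned truncated when the contig edge intervenes.
    """
    tir = extract_tir_window(genomes, gene, upstream=21, downstream=24)
    up = "".join(tir.base_at(k) or "" for k in range(-21, 0))
    down = "".join(tir.base_at(k) or "" for k in range(4, 25))
    out: dict[str, str | None] = {"tir_upstream": up, "tir_downstream": down}
    length = gene.length
    if length < MIN_MIDGENE_LENGTH:
        out["midgene_upstream"] = None
        out["midgene_downstream"] = None
        return out
    cds = extract_tir_window(genomes, gene, upstream=0, downstream=length - 1)
    m = length // 2
    out["midgene_upstream"] = cds.sequence[m - 20 : m]
    out["midgene_downstream"] = cds.sequence[m : m + 20]
    return out


def genome_ratios(
    genomes: Mapping[str, GenomeRecord],
    annotations: Sequence[GeneAnnotation],
    genome_id: str = "genome",
    gene_ids: Iterable[str] | None = None,
) -> TrinucleotideRatios:
    """Aggregate-then-ratio trinucleotide statistics for one genome.

    ``gene_ids`` restricts the analysis to a supplied gene set (e.g. a
    representative set); default is all annotated CDS.  Counts are summed
    across genes and one ratio per window is formed from the aggregates.
    """
    if gene_ids is not None:
        wanted = set(gene_ids)
        annotations = [a for a in annotations if a.gene_id in wanted]
    if not annotations:
        raise ValueError("no genes to analyze")
    counts = {
        w: dict.fromkeys((TARGET,) + NORMALIZERS, 0) for w in WINDOW_NAMES
    }
    n_mid = 0
    for gene in annotations:
        seqs = gene_window_sequences(genomes, gene)
        if seqs["midgene_upstream"] is not None:
            n_mid += 1
        for window, seq in seqs.items():
            if seq is None or len(seq) < 3:
                continue
            for tri in (TARGET,) + NORMALIZERS:
                counts[window][tri] += count_trinucleotides_in_window(seq, tri)
    return TrinucleotideRatios(
        genome_id=genome_id,
        counts=counts,
        n_genes=len(annotations),
        n_genes_midgene=n_mid,
    )


def ratios_table(ratios: Sequence[TrinucleotideRatios]) -> pd.DataFrame:
    """Long-format table of per-genome ratios (one row per genome/window/ratio)."""
    rows = []
    for r in ratios:
        for window in WINDOW_NAMES:
            for norm in NORMALIZERS:
                rows.append(
                    {
                        "genome_id": r.genome_id,
                        "window": window,
                        "ratio": f"{TARGET}/{norm}",
                        "value": r.ratio(window, norm),
                        "n_genes": r.n_genes,
                    }
                )
    return pd.DataFrame(rows)


def phylum_analysis(
    ratios_by_phylum: Mapping[str, Sequence[TrinucleotideRatios]],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-phylum one-sample tests vs 1 and pairwise phylum contrasts.

    For each phylum/window/ratio the per-genome ratios are tested against 1
    with a one-sample t-test; every phylum pair is compared with a Welch
    two-sample t-test.  Bonferroni correction is applied within each family
    (all one-sample tests together; all pairwise tests together).  A
    phylum/window/ratio is flagged ``significant_lt1`` only when adjusted
    p < alpha AND the median ratio is below one.
    """
    one_rows = []
    for phylum, ratio_objs in ratios_by_phylum.items():
        if len(ratio_objs) < 2:
            raise ValueError(f"phylum {phylum!r}: need at least 2 genomes")
        for window in WINDOW_NAMES:
            for norm in NORMALIZERS:
                vals = np.array(
                    [r.ratio(window, norm) for r in ratio_objs], dtype=float
                )
                vals = vals[~np.isnan(vals)]
                if vals.size < 2:
                    continue
                try:
                    res = one_sample_t(vals, 1.0)
                    stat, p = res.statistic, res.p_value
                except ZeroVarianceError:
                    stat, p = np.nan, np.nan
                one_rows.append(
                    {
                        "phylum": phylum,
                        "window": window,
                        "ratio": f"{TARGET}/{norm}",
                        "n_genomes": vals.size,
                        "median": float(np.median(vals)),
                        "statistic": stat,
                        "p_value": p,
                    }
                )
    one = pd.DataFrame(one_rows)
    if not one.empty:
        tested = one["p_value"].notna()
        m = int(tested.sum())
        if m:
            threshold, _ = bonferroni(one.loc[tested, "p_value"].tolist(), alpha)
            one["p_adjusted"] = np.minimum(one["p_value"] * m, 1.0)
            one["significant_lt1"] = (one["p_adjusted"] < alpha) & (one["median"] < 1)
            one.loc[~tested, "significant_lt1"] = False

    pair_rows = []
    for pa, pb in combinations(sorted(ratios_by_phylum), 2):
        for window in WINDOW_NAMES:
            for norm in NORMALIZERS:
                va = np.array(
                    [r.ratio(window, norm) for r in ratios_by_phylum[pa]],
                    dtype=float,
                )
                vb = np.array(
                    [r.ratio(window, norm) for r in ratios_by_phylum[pb]],
                    dtype=float,
                )
                va, vb = va[~np.isnan(va)], vb[~np.isnan(vb)]
                if va.size < 2 or vb.size < 2:
                    continue
                try:
                    res = two_sample_t(va, vb)
                    stat, p = res.statistic, res.p_value
                except ZeroVarianceError:
                    stat, p = np.nan, np.nan
                pair_rows.append(
                    {
                        "phylum_a": pa,
                        "phylum_b": pb,
                        "window": window,
                        "ratio": f"{TARGET}/{norm}",
                        "statistic": stat,
                        "p_value": p,
                    }
                )
    pairwise = pd.DataFrame(pair_rows)
    if not pairwise.empty:
        tested = pairwise["p_value"].notna()
        m = int(tested.sum())
        if m:
            _, _adj = bonferroni(pairwise.loc[tested, "p_value"].tolist(), alpha)
            pairwise["p_adjusted"] = np.minimum(pairwise["p_value"] * m, 1.0)
            pairwise["significant"] = pairwise["p_adjusted"] < alpha
            pairwise.loc[~tested, "significant"] = False
    return one, pairwise
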