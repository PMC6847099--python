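#!/usr/bin/env python
"""Positional nucleotide frequencies across TIRs and octile-1 vs -8 contrasts.

Builds -30..+30 windows for every octile-assigned gene, writes the
all-gene frequency profile, runs the per-position A/C/G/U contrasts with
Bonferroni correction, and reports the A-frequency trend across octiles at
the planted determinant offsets.
"""

from pathlib import Path

import pandas as pd

from tirscope import tir_composition as tc
from tirscope.sequence_io import extract_tir_window, read_annotations, read_genome
from tirscope.stats_core import spearman

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data"
    genomes = read_genome(data / "genome.fasta")
    by_id = {a.gene_id: a for a in read_annotations(data / "annotations.gff3")}
    expression = pd.read_csv(ROOT / "expression.tsv", sep="\t", index_col=0)

    windows_by_octile: dict[int, list] = {}
    for gene_id, octile in expression["octile"].dropna().items():
        windows_by_octile.setdefault(int(octile), []).append(
            extract_tir_window(genomes, by_id[gene_id], 30, 30)
        )

    all_windows = [w for ws in windows_by_octile.values() for w in ws]
    profile = tc.positional_frequencies(all_windows, range(-30, 31))
    profile.to_csv(ROOT / "tir_frequencies_all.tsv", sep="\t")

    for nt in "ACGU":
        contrast = tc.octile_contrast(windows_by_octile, range(-30, 31), nt)
        contrast.to_csv(ROOT / f"tir_contrast_{nt}.tsv", sep="\t", index=False)
        significant = contrast[contrast["significant"].fillna(False)]
        print(f"{nt}: significant octile-1 vs octile-8 positions "
              f"(Bonferroni m={contrast.attrs['bonferroni_m']}): "
              f"{sorted(significant['position'].tolist())}")
    print("note: upstream hits are the planted Kozak-like determinants; "
          "downstream hits (+10..+33) reflect the GC-rich hairpins planted "
          "in low-ARD genes' early CDS")

    trend = pd.DataFrame(
        {f"A@{p}": tc.frequency_by_octile(windows_by_octile, p, "A")
         for p in (-3, -6, -12, -13)}
    )
    trend.to_csv(ROOT / "tir_A_frequency_by_octile.tsv", sep="\t")
    for col in trend.columns:
        r = spearman(trend.index.values.astype(float), trend[col].values)
        print(f"{col}: frequency vs octile Spearman {r:.2f} "
              f"(octile 1 = {trend[col].iloc[0]:.2f}, "
              f"octile 8 = {trend[col].iloc[-1]:.2f})")


if __name__ == "__main__":
    main()
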