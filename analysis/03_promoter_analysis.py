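#!/usr/bin/env python
"""Promoter -7 element discovery, spacing filter, consensus and leaders.

Scans the 50 nt upstream of each TSS for candidate TAHHTTTG-family
elements, histograms element-to-TSS spacing, keeps the 4-5 nt spacing class
as probable promoters, derives the IUPAC consensus from the aligned
frequency matrix, and summarizes mRNA leader lengths.
"""

from pathlib import Path

import pandas as pd

from tirscope import promoters as pm
from tirscope.sequence_io import (
    extract_upstream_of_tss,
    read_annotations,
    read_genome,
    read_tss_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    data = ROOT / "data"
    genomes = read_genome(data / "genome.fasta")
    annotations = read_annotations(data / "annotations.gff3")
    tss_records = read_tss_table(data / "tss.tsv")

    upstream = {t.gene_id: extract_upstream_of_tss(genomes, t, 50)
                for t in tss_records}
    hits = pm.find_candidate_elements(upstream, "consensus_scan")
    hist = pm.spacing_histogram(hits)
    probable = pm.filter_probable_promoters(hits)
    model = pm.build_promoter_model(probable, upstream, flank=10)
    consensus = pm.derive_consensus(model)

    pd.DataFrame(
        [{"gene_id": h.gene_id, "element": h.element_seq,
          "spacing": h.spacing, "score": h.score} for h in hits]
    ).to_csv(ROOT / "promoter_hits.tsv", sep="\t", index=False)
    pd.Series(hist, name="proportion").rename_axis("spacing").to_csv(
        ROOT / "promoter_spacing_histogram.tsv", sep="\t")
    model.frequencies.to_csv(ROOT / "promoter_frequencies.tsv", sep="\t")

    leaders, summary = pm.leader_lengths(tss_records, annotations, threshold=10)
    pd.Series(leaders, name="leader_nt").rename_axis("gene_id").to_csv(
        ROOT / "leader_lengths.tsv", sep="\t")

    print(f"candidate elements: {len(hits)} of {len(upstream)} upstream regions")
    print("spacing histogram:",
          {k: round(v, 3) for k, v in sorted(hist.items())})
    print(f"probable promoters (spacing 4-5): {len(probable)}")
    print(f"consensus over the aligned element: {consensus}")
    print(f"mean leader {summary['mean_leader']:.1f} nt; "
          f"{100 * summary['fraction_over_threshold']:.1f}% of leaders > 10 nt")


if __name__ == "__main__":
    main()
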