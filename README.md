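# tirscope

Downstream analysis of bacterial ribosome profiling centred on the
translation initiation region (TIR), built for organisms — such as members
of the Bacteroidetes — whose mRNAs naturally lack Shine–Dalgarno sequences
and whose initiation determinants therefore have to be read out of sequence
and structure context instead.

Given a genome (FASTA), CDS annotations (GFF3), per-gene ribo-seq and
RNA-seq replicate counts (TSV) and a table of predicted transcriptional
start sites (TSS), the package computes:

* **Average ribosome density (ARD).** Replicates are summed per gene, genes
  are ranked by RNA-seq fragments per nt, the top third forms the
  representative set, both assays are CPM-normalized with the scale factor
  taken over that set, and ARD(g) = ribo_cpm(g) / rna_cpm(g) — a proxy for
  initiation rate, also called translation efficiency.  Representative
  genes are rank-ordered by ARD into octiles (octile 1 = highest).
* **Positional nucleotide composition** over offsets −30..+30 (offset 0 =
  first base of the start codon), with octile-1 vs octile-8 contrasts:
  per-gene 0/1 indicators compared by Welch's t-test per position,
  Bonferroni-corrected across positions.  This is the analysis that
  surfaces Kozak-like determinants (A at −3, −6 and the A-rich −12/−13
  region).
* **Local mRNA secondary structure.** Each −100..+100 window is folded with
  an exact McCaskill-style partition function over nested structures under
  a pair-weight-only model (weights e³, e², e¹ for GC/AU/GU, minimum
  hairpin loop 3 nt), giving per-position probabilities of being paired,
  averaged per octile and contrasted.
* **Promoter −7 elements.** The 50 nt upstream of each TSS is scanned for
  the Bacteroidetes promoter element (seed TANNTTTG; a Gibbs sampler is
  available as a second search mode), candidates are histogrammed by
  element-to-TSS spacing, the 4–5 nt spacing class is kept as probable
  promoters, an IUPAC consensus is derived from the aligned frequency
  matrix, and mRNA leader lengths are summarized.
* **AUG underrepresentation.** Counts of the trinucleotide AUG relative to
  its composition-matched permutations GAU, GUA, AGU in windows −21..−1
  and +4..+24 around the start codon, against 20-nt midgene control
  windows; one ratio per genome per window, with one-sample tests against
  1 and pairwise phylum contrasts for multi-genome collections.

A first-class synthetic-data generator (`tirscope.simulate`) emits genomes,
annotations, TSS tables and negative-binomial count tables with all of the
above effects planted and a ground-truth record per gene, so every stage of
the pipeline can be validated against known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (run them in order; outputs land in `results/`):

```
python analysis/01_simulate_data.py
python analysis/02_expression_octiles.py
...
python analysis/06_trinucleotide_bias.py
```

`01` generates a 5.7-Mnt, 34% GC genome with 5138 genes; the top third by
RNA-seq density gives a 1712-gene representative set and octiles of 214.
`02` prints:

```
rna replicate Spearman: 0.950, 0.950, 0.950
representative set: 1712 of 5138 genes; octile size 214
Spearman(ARD estimate, true efficiency) on the representative set: 0.964
```

i.e. at mean depth 200 reads/gene and negative-binomial dispersion 0.1 the
estimated ARD ranks the planted translation efficiencies almost perfectly.
`04` recovers exactly the planted upstream determinants:

```
A: significant octile-1 vs octile-8 positions (Bonferroni m=61): [-13, -12, -6, -3, ...]
A@-3: frequency vs octile Spearman -0.98 (octile 1 = 0.48, octile 8 = 0.16)
```

(the additional downstream hits are the GC-rich hairpins the generator
plants in low-ARD genes, which `05` picks up as a pairing-probability
contrast at +10..+33).  `03` finds the planted promoters —
spacing histogram `{4: 0.695, 5: 0.305}`, consensus `TAHHTTTG`, mean
leader 33.7 nt with 87.4% over 10 nt — and `06` reports TIR AUG/GAU ratios
near the configured depletion factor 0.6 (0.57 upstream, 0.64 downstream)
with midgene controls at 1.0, and flags all three emulated phylum groups as
significantly below 1 in the upstream TIR window with the planted ordering
(0.52 < 0.68 < 0.78).

## CLI

A thin `tirscope` command wraps the library for shell use:
`tirscope simulate --seed 7 --n-genes 500 --out data/`,
`tirscope expression --genome ... --gff ... --rna ... --ribo ... --tss ... --out out/`,
or `tirscope all --config run.yaml` for a full configured run.  Every run
writes a `manifest.json` with the resolved configuration, seeds, and
per-stage gene-exclusion counts.
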