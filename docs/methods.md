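# Methods

This note documents the models, conventions and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Coordinates and windows

Internal coordinates are 0-based half-open; file interfaces keep each
format's native convention (GFF3 1-based inclusive, and a written GFF3
round-trips byte-for-byte on the coordinate columns).  TIR offsets are
defined with offset 0 on the first nucleotide of the start codon and −1
immediately 5′ of it.  Windows are taken from genomic context on the
gene's strand (transcribed T→U), not clipped at transcript boundaries:
whether a real TIR window should stop at the TSS is ambiguous, so we fold
and count the genomic neighbourhood and record window completeness
instead.  Windows truncated by a contig edge are shortened, never padded,
and flagged.  Positions carrying N are excluded position-wise from
frequency statistics (not gene-wise), which maximizes usable data.

## Expression and octiles

Replicates are summed per gene before any ranking.  The representative set
is the top floor(fraction·n) genes by RNA-seq count per nt (default
fraction 1/3); genes with zero RNA counts are excluded from the ranking
before the cut, and ties at the cut go to the lexicographically smaller
gene id so selection is reproducible.  CPM uses the scale factor from the
representative genes only, applied to all genes, so representative CPM
sums to exactly 1e6.  ARD = ribo_cpm/rna_cpm is undefined (NaN) where
rna_cpm = 0; such genes are excluded from octile assignment.  Octiles have
size floor(n/8); remainder genes (lowest ARD) stay unassigned.  The rule is
inert on set sizes divisible by eight (1712, 1440, 1392) but must be
defined for arbitrary inputs.  The octile count is a parameter, so the
eight-group design is one point in a family.

## Statistics

Positional base-composition contrasts treat each gene as a Bernoulli
indicator (gene has base b at offset k) and compare octiles with Welch's
two-sample t-test; a pooled-variance variant exists for sensitivity
analysis.  Degenerate inputs follow an explicit rule: both samples
constant and equal → statistic 0, p = 1 (e.g. the invariant start-codon
positions); zero variance in only one sample → the position is reported
with NaN p and never flagged significant.  Bonferroni correction uses
m = number of positions actually tested within one panel (61 for
−30..+30 when none are degenerate); the threshold alpha/m and adjusted
values min(1, p·m) are emitted with every table.  For the trinucleotide
phylum analysis, all one-sample tests form one Bonferroni family and all
pairwise tests another, and "significantly < 1" additionally requires the
median below one.  t-tests and Spearman go through scipy.stats; the
Bonferroni arithmetic is cross-checked against statsmodels in the tests.

## RNA folding model

The partition function sums over all pseudoknot-free nested structures
with pair weights w(GC) = e³, w(AU) = e², w(GU) = e (β = 1, weights
ordered by hydrogen-bond count) and at least 3 unpaired nt inside every
hairpin loop; the empty structure has weight 1.  There is no stacking or
loop-entropy term: the quantity of interest is *relative* pairing
propensity across start-codon windows and between gene groups, and the
minimal model admits an exact implementation that is verified against
exhaustive enumeration (inside–outside agreement to ~1e-15 relative on
hundreds of short random sequences).  The inside recursion decomposes each
interval by the pairing status of its last base; the outside pass inverts
the same grammar, giving pair probabilities B·Bout/Z and per-position
probabilities of being paired to anything.  Complexity is O(n³) time and
O(n²) space via column-wise matrix–vector products; a 201-nt window folds
in ~30 ms.  N is treated as unpairable.  Consequences of the simplification
worth knowing: helix ends "breathe" more than under a nearest-neighbour
model (a perfect 8–10 bp hairpin stem shows per-position pairing
probabilities of roughly 0.76–0.94, not >0.99), and absolute probabilities
are not comparable to free-energy folders — an adapter accepting an
external folder's per-position table fills that gap for publication runs.

## Promoter analysis

Promoters are DNA features, so this stage works in the DNA alphabet.  The
consensus scan matches the degenerate seed TANNTTTG and reports a hit when
all six defined positions agree (threshold configurable); ties go to the
most TSS-proximal match.  Spacing is the number of nucleotides strictly
between the element's 3′ base and the TSS; probable promoters are exactly
the spacing 4–5 class.  Element columns are labelled −12..−5 on the
promoter coordinate system.  The IUPAC consensus takes a single base when
its column frequency ≥ 0.9 and otherwise the minimal degenerate code
covering bases above 0.05 — this is the rule under which a column with
A/C/T each ≈ 1/3 and G ≈ 0 reads H.  The Gibbs sampler (one site per
sequence, width 8, pseudocount 0.5, iterations counted as single-sequence
updates) is a documented stand-in for an external motif finder, seeded and
bit-reproducible; the consensus scan is the primary mode.  Leader length
is the number of nucleotides strictly between the TSS and the first base
of the start codon, so a TSS on the start codon gives leader 0
(leaderless); the summary reports the mean and the fraction exceeding a
threshold (default 10 nt).

## Trinucleotide bias

AUG is counted at every start offset (overlaps allowed) in four windows:
−21..−1 and +4..+24 around the start codon (19 start offsets each; the
start codon itself can never be counted because +4 > +2) and the two 20-nt
windows abutting the gene midpoint m = floor(length/2) in mRNA
coordinates, [m−20, m) and [m, m+20).  Genes shorter than 43 nt are
excluded from midgene counts only.  Counts are summed across genes and one
ratio per genome is formed from the aggregates (avoiding per-gene zero
denominators); a per-gene mode is not provided.  The analyzed gene set is
configurable: all annotated CDS (used for multi-genome collections) or a
supplied representative list.

## Synthetic-data generator

The generator's defaults are the study conditions; every stochastic choice
derives from the mandatory seed.

* Genome: genes with uniform lengths 300–1500 nt (rounded up to a codon
  multiple) placed non-overlapping on both strands with 40–120 nt
  intergenic pads, background GC 0.34.  Start codons are always AUG.
* Promoters and leaders: every gene gets a TAHHTTTG element (H drawn
  uniformly from A/C/T) at spacing 4 (70%) or 5 (30%), then the TSS.
  Leaders are log-normal (meanlog ln 27, sdlog 0.72) with 4% leaderless
  genes, giving a mean leader of ~33 nt with ~87% over 10 nt.
* Expression and efficiency: per-gene transcript abundance is log-normal
  with σ = 2.0 (three to four orders of magnitude, typical of bulk
  RNA-seq); true translation efficiency is log-normal with σ = 1.0
  (a ~50-fold central range, a realistic breadth for bacterial TE).
* Kozak-like determinants: at offsets −3, −6, −12, −13 the probability of
  A is base + effect·(efficiency percentile − ½), clipped to [0.02, 0.98],
  with effects 0.4 / 0.3 / 0.35 and a constitutive +0.10 at −12/−13 (the
  A-rich motif characteristic of the phylum).  Offsets that fall at or
  upstream of the TSS (very short leaders) are left untouched, which also
  guarantees planted promoters are never overwritten.
* AUG depletion: inside −21..−1 and +4..+24 each AUG is kept with
  probability `aug_depletion` (default 0.6); otherwise only its G is
  redrawn from the background non-G composition.  The single-base edit
  leaves planted adenines intact and minimally disturbs overlapping
  GAU/GUA/AGU occurrences — any AUG-removing edit necessarily removes the
  AUG inside e.g. GAUG, so perfect denominator neutrality is impossible —
  and the realized TIR AUG/GAU ratio lands within a few percent of the
  configured factor while midgene windows stay neutral.
* Hairpins: with probability `hairpin_fraction_low_ard` (default 0,
  i.e. off), genes in the lowest efficiency quartile receive a 10-bp
  GC-rich stem–4-nt-loop hairpin at offsets +10..+33 — inside the local
  folding window, clear of the promoter and of the planted upstream
  determinants.
* Counts: RNA-seq means ∝ abundance × length, ribo-seq means carry the
  extra efficiency factor, both scaled to a configured mean depth per gene
  per replicate (default 200, 3 replicates per assay); replicate counts
  are negative binomial with variance μ + αμ² (α default 0.1; Poisson
  below α = 1e-8).

What the generator does **not** emulate: operon structure (one TSS per
gene), non-AUG start codons, read-level artefacts (mapping bias, rRNA
contamination, footprint periodicity), continuous structure–efficiency
coupling (hairpins are a planted subpopulation), and codon-level selection.
Passing recovery tests therefore demonstrates that the estimators are
correct and well-powered under the assumed statistical structure, not that
the biology of any real genome is this clean.

## Problem sizes and determinism

The analysis scripts run at the study scale (5138 genes; 1712-gene
representative set; 214 per octile; 150 genes folded per octile in the
structure stage).  The test suite and acceptance script use the sizes each
check needs: 200 random sequences of length ≤ 14 for the folding oracle,
500 uniform-composition genes for ratio neutrality, 2000 genes for
depletion-ratio recovery (a ratio of two ~100–600 counts needs that many
genes for a stable estimate), 900 genes for ARD recovery, 1712 for the
determinant contrast, 200 planted promoters plus 50 decoys, and 25 windows
per group for the structure contrast.  Every pipeline rerun on identical
inputs and configuration is bit-identical; all randomness flows from
explicit seeds recorded in the run manifest.

## Known limitations

Octile contrasts on indicator data are approximate at extreme frequencies
(a position where one octile is perfectly constant is reported but not
tested); an exact binomial alternative is a possible extension, as is FDR
control in place of Bonferroni.  The folding model ignores
stacking/loop entropies by design.  TSS prediction, read alignment and
counting are out of scope: counts tables and TSS tables are consumed as
inputs.
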