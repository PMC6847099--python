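"""Synthetic genomes, annotations, TSS tables and count tables with ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every pipeline stage can be checked against a known truth:

* an AT-rich genome (default 34% GC) carrying non-overlapping genes on both
  strands, each preceded by a planted promoter -7 element (TAHHTTTG) at a
  sampled element-to-TSS spacing and an mRNA leader with a realistic length
  distribution (mean about 33 nt, a few percent leaderless);
* per-gene true translation efficiencies (log-normal); the probability of
  adenine at TIR offsets -3, -6, -12, -13 increases with the efficiency
  percentile, mirroring the Kozak-like determinants the analysis should
  recover;
* AUG trinucleotides inside the TIR windows (-21..-1 and +4..+24) are kept
  with probability ``aug_depletion``; otherwise only the G is redrawn from
  the background non-G composition.  The single-base edit is the minimal
  perturbation: it leaves planted upstream adenines untouched and disturbs
  overlapping GAU/GUA/AGU normalizer occurrences as little as any
  AUG-removing edit can, so the realized TIR AUG/GAU ratio tracks the
  configured depletion factor (within a few percent) while midgene windows
  stay neutral;
* optionally, a GC-rich hairpin is embedded in the early coding sequence
  (offsets +10..+33, inside the local folding window) of a fraction of
  low-efficiency genes;
* replicate counts are negative binomial with variance mu + alpha*mu**2,
  with ribo-seq means proportional to (expression x length x efficiency).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression import CountsTable
from .sequence_io import (
    GeneAnnotation,
    GenomeRecord,
    TSSRecord,
    reverse_complement,
)

DNA = "ACGT"

__all__ = [
    "SyntheticConfig",
    "GeneTruth",
    "GroundTruth",
    "SyntheticBundle",
    "generate_genome",
    "generate_counts",
    "generate_promoter_set",
    "generate_structure_fixture",
    "write_bundle",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    ``depth`` is the mean read count per gene per replicate.
    ``log_efficiency_sigma`` is the standard deviation of natural-log true
    translation efficiency (1.0 spans roughly a 50-fold central range,
    typical of bacterial translation-efficiency distributions);
    ``log_expression_sigma`` plays the same role for transcript abundance
    (2.0 spans three to four orders of magnitude, typical of bulk RNA-seq).
    Effects are the slopes linking efficiency percentile to A-probability at
    the corresponding TIR offsets; magnitudes default to roughly what the
    octile profiles of a Bacteroidetes genome show.
    """

    seed: int
    n_genes: int = 500
    gene_length: tuple[int, int] = (300, 1500)
    gc_content: float = 0.34
    n_replicates: int = 3
    depth: float = 200.0
    nb_dispersion: float = 0.1
    log_efficiency_sigma: float = 1.0
    log_expression_sigma: float = 2.0
    a3_effect: float = 0.4
    a6_effect: float = 0.3
    a12_13_effect: float = 0.35
    a12_13_base_boost: float = 0.10
    aug_depletion: float = 0.6
    promoter_spacing_probs: dict[int, float] = field(
        default_factory=lambda: {4: 0.7, 5: 0.3}
    )
    hairpin_fraction_low_ard: float = 0.0
    leader_meanlog: float = float(np.log(27.0))
    leader_sdlog: float = 0.72
    leaderless_fraction: float = 0.04
    intergenic_length: tuple[int, int] = (40, 120)
    contig_id: str = "synthetic_contig_1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if not 0 < self.aug_depletion <= 1:
            raise ValueError("aug_depletion must be in (0, 1]")
        total = sum(self.promoter_spacing_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("promoter spacing proportions must sum to 1")


@dataclass
class GeneTruth:
    gene_id: str
    strand: str
    length: int
    true_efficiency: float
    efficiency_percentile: float
    true_octile: int
    expression_level: float
    element_seq: str
    spacing: int
    leader: int  # nt strictly between TSS and start codon
    hairpin: bool


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth]
    aug_depletion: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "aug_depletion": self.aug_depletion,
            "genes": {g: asdict(t) for g, t in self.genes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        genes = {g: GeneTruth(**d) for g, d in payload["genes"].items()}
        return cls(genes=genes, aug_depletion=payload["aug_depletion"])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.genes.values()]).set_index(
            "gene_id"
        )


@dataclass
class SyntheticBundle:
    genomes: dict[str, GenomeRecord]
    annotations: list[GeneAnnotation]
    tss_records: list[TSSRecord]
    ground_truth: GroundTruth


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> list[str]:
    return list(rng.choice(list(DNA), size=n, p=_base_probs(gc)))


def _true_octiles(efficiency: np.ndarray, n_octiles: int = 8) -> np.ndarray:
    """Octile labels by descending true efficiency (same remainder rule as
    the estimator: the floor(n/8)-sized groups, lowest-efficiency remainder
    unassigned and labeled 0)."""
    n = efficiency.size
    size = n // n_octiles
    order = np.argsort(-efficiency, kind="stable")
    octiles = np.zeros(n, dtype=int)
    for o in range(n_octiles):
        octiles[order[o * size : (o + 1) * size]] = o + 1
    return octiles


def generate_genome(config: SyntheticConfig) -> SyntheticBundle:
    """Emit a genome, annotations, TSS records and the ground truth."""
    rng = np.random.default_rng([config.seed, 101])
    n = config.n_genes
    gc = config.gc_content
    eff = np.exp(rng.normal(0.0, config.log_efficiency_sigma, size=n))
    expr = np.exp(rng.normal(0.0, config.log_expression_sigma, size=n))
    order = np.argsort(eff, kind="stable")
    pct = np.empty(n)
    pct[order] = (np.arange(n) + 0.5) / n
    octiles = _true_octiles(eff)

    spacings = np.array(sorted(config.promoter_spacing_probs))
    spacing_p = np.array(
        [config.promoter_spacing_probs[s] for s in spacings], dtype=float
    )

    base_a = (1 - gc) / 2
    non_a = np.array([gc / 2, gc / 2, (1 - gc) / 2])
    non_a = non_a / non_a.sum()  # C, G, T given "not A"
    no_g = np.array([(1 - gc) / 2, gc / 2, (1 - gc) / 2])
    no_g = no_g / no_g.sum()  # A, C, T given "not G"

    chunks: list[str] = []
    annotations: list[GeneAnnotation] = []
    tss_records: list[TSSRecord] = []
    truths: dict[str, GeneTruth] = {}
    offset = 0
    for g in range(n):
        gene_id = f"gene{g + 1:05d}"
        length = int(rng.integers(config.gene_length[0], config.gene_length[1] + 1))
        if length % 3:
            length += 3 - length % 3
        strand = "+" if rng.random() < 0.5 else "-"
        spacing = int(rng.choice(spacings, p=spacing_p))
        element = "TA" + "".join(rng.choice(list("ACT"), size=2)) + "TTTG"
        leaderless = rng.random() < config.leaderless_fraction
        if leaderless:
            leader = 0
        else:
            leader = max(
                1,
                int(round(rng.lognormal(config.leader_meanlog, config.leader_sdlog))),
            )

        up_pad = _random_dna(
            rng, int(rng.integers(*config.intergenic_length)), gc
        )
        spacer = _random_dna(rng, spacing, gc)
        between = [] if leaderless else _random_dna(rng, 1 + leader, gc)
        cds = ["A", "T", "G"] + _random_dna(rng, length - 3, gc)
        down_pad = _random_dna(rng, int(rng.integers(*config.intergenic_length)), gc)

        cassette = up_pad + list(element) + spacer + between + cds + down_pad
        cds_start = len(up_pad) + 8 + spacing + len(between)
        tss_idx = len(up_pad) + 8 + spacing  # first transcript base

        # hairpin in the early CDS (offsets +10..+33) of some low-efficiency
        # genes: inside the local folding window, clear of the promoter and
        # of the planted upstream determinants
        hairpin = bool(
            pct[g] < 0.25 and rng.random() < config.hairpin_fraction_low_ard
        )
        if hairpin:
            stem = list(rng.choice(["G", "C"], size=10))
            loop = _random_dna(rng, 4, gc)
            hp = stem + loop + list(reverse_complement("".join(stem)))
            pos0 = cds_start + 10
            cassette[pos0 : pos0 + 24] = hp

        # Kozak-like planting: A-probability rises with efficiency percentile
        for off, effect, boost in (
            (3, config.a3_effect, 0.0),
            (6, config.a6_effect, 0.0),
            (12, config.a12_13_effect, config.a12_13_base_boost),
            (13, config.a12_13_effect, config.a12_13_base_boost),
        ):
            p_a = float(np.clip(base_a + boost + effect * (pct[g] - 0.5), 0.02, 0.98))
            pos = cds_start - off
            if pos <= tss_idx:
                continue  # offset lies outside the transcript (short leader)
            if rng.random() < p_a:
                cassette[pos] = "A"
            else:
                cassette[pos] = str(rng.choice(list("CGT"), p=non_a))

        # AUG depletion inside the two TIR windows (start offsets fully inside)
        if config.aug_depletion < 1.0:
            for w0, w1 in (
                (cds_start - 21, cds_start),
                (cds_start + 4, cds_start + 25),
            ):
                for i in range(w0, w1 - 2):
                    if "".join(cassette[i : i + 3]) == "ATG":
                        if rng.random() >= config.aug_depletion:
                            # redraw only the G (minimal edit: leaves planted
                            # upstream adenines and most overlapping
                            # normalizer trinucleotides intact)
                            cassette[i + 2] = str(rng.choice(list("ACT"), p=no_g))

        cassette_str = "".join(cassette)
        clen = len(cassette_str)
        if strand == "+":
            chunks.append(cassette_str)
            start = offset + cds_start
            annotations.append(
                GeneAnnotation(gene_id, config.contig_id, start, start + length, "+")
            )
            tss_pos = offset + tss_idx
        else:
            chunks.append(reverse_complement(cassette_str))
            start = offset + clen - (cds_start + length)
            annotations.append(
                GeneAnnotation(
                    gene_id, config.contig_id, start, start + length, "-"
                )
            )
            tss_pos = offset + clen - 1 - tss_idx
        tss_records.append(
            TSSRecord(gene_id, config.contig_id, tss_pos, strand)
        )
        truths[gene_id] = GeneTruth(
            gene_id=gene_id,
            strand=strand,
            length=length,
            true_efficiency=float(eff[g]),
            efficiency_percentile=float(pct[g]),
            true_octile=int(octiles[g]),
            expression_level=float(expr[g]),
            element_seq=element,
            spacing=spacing,
            leader=leader,
            hairpin=hairpin,
        )
        offset += clen

    genome = GenomeRecord(config.contig_id, "".join(chunks))
    return SyntheticBundle(
        genomes={config.contig_id: genome},
        annotations=annotations,
        tss_records=tss_records,
        ground_truth=GroundTruth(genes=truths, aug_depletion=config.aug_depletion),
    )


def _nb_draw(
    rng: np.random.Generator, mu: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial with variance mu + dispersion * mu^2."""
    mu = np.maximum(mu, 1e-12)
    if dispersion < 1e-8:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_counts(
    config: SyntheticConfig, ground_truth: GroundTruth
) -> tuple[CountsTable, CountsTable]:
    """Replicate count tables for both assays, consistent with the truth.

    RNA-seq means are proportional to expression x length; ribo-seq means
    carry the additional factor of true efficiency, so estimated ARD tracks
    the planted efficiencies.
    """
    rng = np.random.default_rng([config.seed, 202])
    frame = ground_truth.frame()
    genes = list(frame.index)
    expr = frame["expression_level"].values
    length = frame["length"].values.astype(float)
    eff = frame["true_efficiency"].values
    w_rna = expr * length
    w_ribo = expr * length * eff
    mu_rna = config.depth * w_rna / w_rna.mean()
    mu_ribo = config.depth * w_ribo / w_ribo.mean()
    rna = {
        f"rna_rep{r + 1}": _nb_draw(rng, mu_rna, config.nb_dispersion)
        for r in range(config.n_replicates)
    }
    ribo = {
        f"ribo_rep{r + 1}": _nb_draw(rng, mu_ribo, config.nb_dispersion)
        for r in range(config.n_replicates)
    }
    rna_table = CountsTable("rna", pd.DataFrame(rna, index=genes))
    ribo_table = CountsTable("ribo", pd.DataFrame(ribo, index=genes))
    return rna_table, ribo_table


def generate_promoter_set(
    seed: int,
    n_planted: int = 200,
    n_decoys: int = 50,
    spacing_probs: Mapping[int, float] | None = None,
    seq_length: int = 50,
    gc_content: float = 0.34,
) -> tuple[dict[str, str], dict[str, tuple[str, int]]]:
    """Upstream 50-nt sequences with planted TAHHTTTG elements plus decoys.

    Returns (sequences keyed by id, truth: id -> (element, spacing) for
    planted entries only).
    """
    spacing_probs = dict(spacing_probs or {4: 0.7, 5: 0.3})
    rng = np.random.default_rng([seed, 303])
    spacings = np.array(sorted(spacing_probs))
    probs = np.array([spacing_probs[s] for s in spacings], dtype=float)
    probs /= probs.sum()
    seqs: dict[str, str] = {}
    truth: dict[str, tuple[str, int]] = {}
    for i in range(n_planted):
        sid = f"tss{i + 1:04d}"
        seq = _random_dna(rng, seq_length, gc_content)
        s = int(rng.choice(spacings, p=probs))
        element = "TA" + "".join(rng.choice(list("ACT"), size=2)) + "TTTG"
        start = seq_length - 8 - s
        seq[start : start + 8] = list(element)
        seqs[sid] = "".join(seq)
        truth[sid] = (element, s)
    for i in range(n_decoys):
        sid = f"decoy{i + 1:04d}"
        seqs[sid] = "".join(_random_dna(rng, seq_length, gc_content))
    return seqs, truth


def generate_structure_fixture(
    seed: int,
    n_per_group: int = 25,
    upstream: int = 100,
    downstream: int = 100,
    stem_length: int = 10,
) -> dict[str, list[str]]:
    """RNA window fixtures for the structure contrast.

    "structured" windows carry a GC-rich hairpin (stem of ``stem_length``
    base pairs, 4-nt loop) just upstream of the start codon; "unstructured"
    windows are plain AT-rich random sequence.  Both have AUG at offsets
    0..2 and total length upstream + downstream + 1.
    """
    rng = np.random.default_rng([seed, 404])
    total = upstream + downstream + 1

    def background() -> list[str]:
        seq = _random_dna(rng, total, 0.25)
        seq[upstream : upstream + 3] = ["A", "T", "G"]
        return seq

    groups: dict[str, list[str]] = {"structured": [], "unstructured": []}
    hp_len = 2 * stem_length + 4
    for _ in range(n_per_group):
        groups["unstructured"].append("".join(background()).replace("T", "U"))
    for _ in range(n_per_group):
        seq = background()
        stem = list(rng.choice(["G", "C"], size=stem_length))
        loop = _random_dna(rng, 4, 0.25)
        hp = stem + loop + list(reverse_complement("".join(stem)))
        pos0 = upstream - 10 - hp_len  # hairpin ends 10 nt upstream of AUG
        seq[pos0 : pos0 + hp_len] = hp
        groups["structured"].append("".join(seq).replace("T", "U"))
    return groups


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + GFF3 + TSS TSV + ground-truth JSON; returns the paths."""
    from .sequence_io import write_annotations, write_genome, write_tss_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "genome.fasta",
        "gff": outdir / "annotations.gff3",
        "tss": outdir / "tss.tsv",
        "truth": outdir / "ground_truth.json",
    }
    write_genome(paths["fasta"], bundle.genomes)
    write_annotations(paths["gff"], bundle.annotations)
    write_tss_table(paths["tss"], bundle.tss_records)
    bundle.ground_truth.to_json(paths["truth"])
    return paths
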