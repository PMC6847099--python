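"""Promoter -7 element discovery, spacing filter, consensus, leader lengths.

Bacteroidetes housekeeping promoters carry a conserved 8-nt "-7 element"
(historical consensus TANNTTTG) a few nucleotides upstream of the TSS,
recognized by the sigma-ABfr holoenzyme.  This module searches the 50 nt
upstream of predicted TSSs for candidate elements, histograms the
element-to-TSS spacing, keeps the 4-5 nt spacing class as probable
promoters, aligns them into a frequency matrix, and derives an IUPAC
consensus.  Two search modes are provided: a degenerate-consensus scan
seeded with TANNTTTG, and a width-8 Gibbs motif sampler (one occurrence per
sequence).

Spacing convention: the number of nucleotides strictly between the
element's 3' base and the TSS, so "4 or 5 nt spacing" means 4-5 intervening
bases.  Element positions are labeled -12..-5 on the promoter coordinate
system.  All sequences here are DNA (promoters are DNA features).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import GeneAnnotation, TSSRecord

DNA_BASES = "ACGT"
SEED_PATTERN = "TANNTTTG"
ELEMENT_WIDTH = 8
ELEMENT_LABEL_START = -12  # element spans promoter coordinates -12..-5

IUPAC = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("ACG"): "V",
    frozenset("ACT"): "H",
    frozenset("AGT"): "D",
    frozenset("CGT"): "B",
    frozenset("ACGT"): "N",
}

__all__ = [
    "MotifHit",
    "PromoterModel",
    "GibbsParams",
    "find_candidate_elements",
    "spacing_histogram",
    "filter_probable_promoters",
    "build_promoter_model",
    "derive_consensus",
    "leader_lengths",
]


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    element_seq: str
    spacing: int  # nt strictly between element 3' end and the TSS
    score: float
    start: int  # 0-based start of the element within the upstream sequence

    def __post_init__(self) -> None:
        if len(self.element_seq) != ELEMENT_WIDTH:
            raise ValueError("element must be exactly 8 nt")
        if self.spacing < 0:
            raise ValueError("negative spacing")


@dataclass
class PromoterModel:
    """Aligned count/frequency matrices over the element plus optional flanks."""

    width: int
    positions: list[int]  # promoter-coordinate label per column
    counts: pd.DataFrame  # index A,C,G,T; columns = positions
    frequencies: pd.DataFrame
    n_sequences: int


def _match_score(window: str, pattern: str) -> int:
    """Number of agreeing non-N pattern positions."""
    return sum(1 for w, p in zip(window, pattern) if p != "N" and w == p)


def _scan_sequence(
    seq: str, pattern: str, min_score: int
) -> tuple[int, int] | None:
    """Best-scoring match position; ties go to the most TSS-proximal start."""
    width = len(pattern)
    best: tuple[int, int] | None = None
    for start in range(len(seq) - width + 1):
        score = _match_score(seq[start : start + width], pattern)
        if score >= min_score and (best is None or score >= best[1]):
            if best is None or score > best[1] or start > best[0]:
                best = (start, score)
    return best


@dataclass(frozen=True)
class GibbsParams:
    """Gibbs site-sampler settings (one element per sequence).

    ``iterations`` counts single-sequence resampling steps; convergence on
    strongly planted motifs takes a few sweeps, so the default covers several
    full passes over typical input sizes.
    """

    width: int = ELEMENT_WIDTH
    iterations: int = 2000
    restarts: int = 20
    pseudocount: float = 0.5
    seed: int = 0


def find_candidate_elements(
    upstream_seqs: Mapping[str, str],
    mode: str = "consensus_scan",
    seed_pattern: str = SEED_PATTERN,
    min_score: int | None = None,
    gibbs: GibbsParams | None = None,
) -> list[MotifHit]:
    """Search each upstream sequence for its best candidate -7 element.

    consensus_scan: best match to the degenerate seed pattern, reported when
    at least ``min_score`` of the defined (non-N) positions agree (default:
    all of them).  gibbs: width-8 Gibbs sampler; one site per sequence with
    a log-odds score.  In both modes at most one hit per gene is returned.
    """
    if not upstream_seqs:
        raise ValueError("no upstream sequences given")
    for g, s in upstream_seqs.items():
        if len(s) < ELEMENT_WIDTH:
            raise ValueError(f"upstream sequence for {g!r} shorter than 8 nt")
    if mode == "consensus_scan":
        defined = sum(1 for c in seed_pattern if c != "N")
        threshold = defined if min_score is None else min_score
        hits = []
        for gene_id in sorted(upstream_seqs):
            seq = upstream_seqs[gene_id]
            found = _scan_sequence(seq, seed_pattern, threshold)
            if found is None:
                continue
            start, score = found
            hits.append(
                MotifHit(
                    gene_id=gene_id,
                    element_seq=seq[start : start + len(seed_pattern)],
                    spacing=len(seq) - (start + len(seed_pattern)),
                    score=float(score),
                    start=start,
                )
            )
        return hits
    if mode == "gibbs":
        return _gibbs_search(upstream_seqs, gibbs or GibbsParams())
    raise ValueError(f"unknown mode {mode!r}")


def _gibbs_search(
    upstream_seqs: Mapping[str, str], params: GibbsParams
) -> list[MotifHit]:
    rng = np.random.default_rng(params.seed)
    gene_ids = sorted(upstream_seqs)
    enc = {b: i for i, b in enumerate(DNA_BASES)}
    seqs = [
        np.array([enc.get(c, -1) for c in upstream_seqs[g]], dtype=np.int64)
        for g in gene_ids
    ]
    w = params.width
    n_pos = [s.size - w + 1 for s in seqs]
    # windows[i][p] = base codes of the width-w window at position p
    windows = [
        np.stack([s[p : p + w] for p in range(np_)], axis=0)
        for s, np_ in zip(seqs, n_pos)
    ]
    all_bases = np.concatenate(seqs)
    bg = np.bincount(all_bases[all_bases >= 0], minlength=4).astype(float)
    bg /= bg.sum()

    def counts_for(positions: np.ndarray) -> np.ndarray:
        c = np.full((4, w), params.pseudocount)
        for i, p in enumerate(positions):
            win = windows[i][p]
            for k in range(w):
                if win[k] >= 0:
                    c[win[k], k] += 1
        return c

    def log_odds(c: np.ndarray) -> np.ndarray:
        freqs = c / c.sum(axis=0, keepdims=True)
        return np.log(freqs) - np.log(bg)[:, None]

    best_positions = None
    best_score = -np.inf
    n_seq = len(seqs)
    for _ in range(params.restarts):
        positions = np.array([rng.integers(0, m) for m in n_pos])
        counts = counts_for(positions)
        for it in range(params.iterations):
            i = it % n_seq
            win = windows[i][positions[i]]
            for k in range(w):  # leave one sequence out
                if win[k] >= 0:
                    counts[win[k], k] -= 1
            lo = log_odds(counts)
            # score every candidate site of sequence i
            scores = np.zeros(n_pos[i])
            for k in range(w):
                col = windows[i][:, k]
                valid = col >= 0
                scores[valid] += lo[col[valid], k]
            probs = np.exp(scores - scores.max())
            probs /= probs.sum()
            positions[i] = rng.choice(n_pos[i], p=probs)
            win = windows[i][positions[i]]
            for k in range(w):
                if win[k] >= 0:
                    counts[win[k], k] += 1
        lo = log_odds(counts)
        total = 0.0
        for i in range(n_seq):
            win = windows[i][positions[i]]
            for k in range(w):
                if win[k] >= 0:
                    total += lo[win[k], k]
        if total > best_score:
            best_score = total
            best_positions = positions.copy()

    counts = counts_for(best_positions)
    lo = log_odds(counts)
    hits = []
    for i, gene_id in enumerate(gene_ids):
        p = int(best_positions[i])
        seq = upstream_seqs[gene_id]
        win = windows[i][p]
        score = float(sum(lo[win[k], k] for k in range(w) if win[k] >= 0))
        hits.append(
            MotifHit(
                gene_id=gene_id,
                element_seq=seq[p : p + w],
                spacing=len(seq) - (p + w),
                score=score,
                start=p,
            )
        )
    return hits


def spacing_histogram(hits: Sequence[MotifHit]) -> dict[int, float]:
    """Proportion of candidate elements at each element-to-TSS spacing."""
    if not hits:
        raise ValueError("no hits")
    counts: dict[int, int] = {}
    for h in hits:
        counts[h.spacing] = counts.get(h.spacing, 0) + 1
    n = len(hits)
    return {k: counts[k] / n for k in sorted(counts)}


def filter_probable_promoters(
    hits: Iterable[MotifHit], spacings: tuple[int, ...] = (4, 5)
) -> list[MotifHit]:
    """Keep exactly the candidates with 4 or 5 nt spacing (probable promoters)."""
    return [h for h in hits if h.spacing in spacings]


def build_promoter_model(
    hits: Sequence[MotifHit],
    upstream_seqs: Mapping[str, str],
    flank: int = 0,
) -> PromoterModel:
    """Align hits on the element and build count/frequency matrices.

    Columns cover the element (promoter coordinates -12..-5) plus ``flank``
    positions on each side; flank columns may have smaller n where source
    sequences end.
    """
    if len(hits) < 2:
        raise ValueError("need at least two hits")
    positions = list(
        range(ELEMENT_LABEL_START - flank, ELEMENT_LABEL_START + ELEMENT_WIDTH + flank)
    )
    counts = pd.DataFrame(0, index=list(DNA_BASES), columns=positions)
    for h in hits:
        seq = upstream_seqs[h.gene_id]
        for col_idx, label in enumerate(positions):
            i = h.start - flank + col_idx
            if 0 <= i < len(seq) and seq[i] in DNA_BASES:
                counts.loc[seq[i], label] += 1
    totals = counts.sum(axis=0)
    frequencies = counts / totals.replace(0, np.nan)
    return PromoterModel(
        width=ELEMENT_WIDTH,
        positions=positions,
        counts=counts,
        frequencies=frequencies,
        n_sequences=len(hits),
    )


def derive_consensus(
    model: PromoterModel,
    invariant_threshold: float = 0.9,
    absent_threshold: float = 0.05,
    element_only: bool = True,
) -> str:
    """IUPAC consensus from the frequency matrix.

    A column becomes a single base when that base's frequency reaches
    ``invariant_threshold``; otherwise it becomes the minimal IUPAC code
    covering every base whose frequency exceeds ``absent_threshold`` (e.g. H
    when only G is effectively absent).
    """
    if not 0 < absent_threshold < 1 or not 0.5 < invariant_threshold < 1:
        raise ValueError("thresholds out of range")
    cols = model.positions
    if element_only:
        cols = [
            p
            for p in cols
            if ELEMENT_LABEL_START <= p < ELEMENT_LABEL_START + ELEMENT_WIDTH
        ]
    letters = []
    for p in cols:
        freqs = model.frequencies[p]
        if freqs.isna().all():
            letters.append("N")
            continue
        top = freqs.idxmax()
        if freqs[top] >= invariant_threshold:
            letters.append(top)
            continue
        present = frozenset(b for b in DNA_BASES if freqs[b] > absent_threshold)
        if not present:
            present = frozenset([top])
        letters.append(IUPAC[present])
    return "".join(letters)


def leader_lengths(
    tss_records: Sequence[TSSRecord],
    genes: Sequence[GeneAnnotation],
    threshold: int = 10,
) -> tuple[dict[str, int], dict[str, float]]:
    """Per-gene mRNA leader length and summary statistics.

    The leader is the number of nucleotides strictly between the TSS and the
    first base of the start codon; a TSS on the start codon itself gives
    leader 0 (leaderless).  The summary reports the mean and the fraction of
    leaders longer than ``threshold`` nt.
    """
    by_id = {g.gene_id: g for g in genes}
    leaders: dict[str, int] = {}
    for tss in tss_records:
        gene = by_id.get(tss.gene_id)
        if gene is None:
            continue
        if tss.strand != gene.strand:
            raise ValueError(f"TSS strand mismatch for gene {gene.gene_id!r}")
        if gene.strand == "+":
            dist = gene.start - tss.tss_position
        else:
            dist = tss.tss_position - (gene.end - 1)
        if dist < 0:
            raise ValueError(f"TSS downstream of start codon for {gene.gene_id!r}")
        leaders[gene.gene_id] = max(0, dist - 1)
    if not leaders:
        raise ValueError("no TSS records matched the annotation set")
    vals = np.array(list(leaders.values()), dtype=float)
    summary = {
        "n": float(vals.size),
        "mean_leader": float(vals.mean()),
        "fraction_over_threshold": float((vals > threshold).mean()),
        "threshold": float(threshold),
    }
    return leaders, summary
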