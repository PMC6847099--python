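"""Base-pairing probabilities from an exact nested-structure partition function.

The folding model is deliberately minimal: every admissible base pair (GC,
AU, GU by default) carries a fixed Boltzmann weight, hairpin loops must
enclose at least ``min_hairpin`` unpaired nucleotides, and pseudoknots are
excluded.  The partition function

    Z = sum over all nested structures of prod over pairs of w(pair)

(the empty structure contributes 1) and the per-position probability of
being paired to anything are computed exactly by an inside-outside dynamic
program in O(n^3) time and O(n^2) space.  There is no stacking or loop
entropy: the aim is relative pairing propensity across start-codon windows,
not free-energy prediction, and the simple model is verifiable against
exhaustive enumeration.  Results from an external folder can be substituted
through the same :class:`PairingProfile` container for publication-grade
runs.

Inside recursion, over half-open intervals [i, j) and with
B(k, l) = w(k, l) * E(k+1, l) the weight of structures on [k, l] closed by
the pair (k, l):

    E(i, j) = E(i, j-1) + sum_k E(i, k) * B(k, j-1)

which decomposes every structure uniquely by the pairing status of the last
position.  The outside pass inverts the same grammar, giving pair
probabilities p(k, l) = B(k, l) * Bout(k, l) / Z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .sequence_io import GeneAnnotation, GenomeRecord, extract_tir_window
from .stats_core import TestResult, ZeroVarianceError, bonferroni, two_sample_t

RNA_ALPHABET = "ACGU"

__all__ = [
    "FoldingModel",
    "PairingProfile",
    "partition_function",
    "fold_tir",
    "average_pairing_by_set",
]


@dataclass(frozen=True)
class FoldingModel:
    """Pair-weight-only energy model.

    ``pair_weights`` maps unordered pair types (two-letter strings, e.g.
    "GC") to Boltzmann weights.  Defaults are exp(3), exp(2), exp(1) for
    GC, AU, GU, i.e. beta = 1 with pair energies proportional to the number
    of hydrogen bonds.  ``min_hairpin`` is the minimum number of unpaired
    nucleotides inside any loop (3, the steric minimum).
    """

    pair_weights: Mapping[str, float] = field(
        default_factory=lambda: {
            "GC": math.exp(3.0),
            "AU": math.exp(2.0),
            "GU": math.exp(1.0),
        }
    )
    min_hairpin: int = 3

    def __post_init__(self) -> None:
        if self.min_hairpin < 3:
            raise ValueError("min_hairpin must be >= 3")
        for k, w in self.pair_weights.items():
            if not (np.isfinite(w) and w > 0):
                raise ValueError(f"pair weight {k}: must be finite and > 0")

    def weight_matrix(self) -> np.ndarray:
        """5x5 symmetric weight lookup over A,C,G,U,N (N never pairs)."""
        order = {b: i for i, b in enumerate(RNA_ALPHABET + "N")}
        mat = np.zeros((5, 5))
        for pair, w in self.pair_weights.items():
            a, b = pair[0], pair[1]
            mat[order[a], order[b]] = w
            mat[order[b], order[a]] = w
        return mat


@dataclass(frozen=True)
class PairingProfile:
    """Per-position probability of being paired, indexed by TIR offset."""

    gene_id: str
    offset_start: int
    p_paired: np.ndarray
    complete: bool = True

    @property
    def offsets(self) -> range:
        return range(self.offset_start, self.offset_start + len(self.p_paired))


def _encode(seq: str) -> np.ndarray:
    order = {b: i for i, b in enumerate(RNA_ALPHABET + "N")}
    try:
        return np.array([order[c] for c in seq], dtype=np.int64)
    except KeyError:
        bad = sorted(set(seq) - set(RNA_ALPHABET + "N"))
        raise ValueError(f"illegal characters in RNA sequence: {bad!r}")


def partition_function(
    seq: str, model: FoldingModel | None = None
) -> tuple[float, np.ndarray]:
    """Exact Z and per-position pairing probabilities for one RNA sequence.

    'N' is accepted and treated as unpairable.  Probabilities are exact to
    floating precision; positions that cannot pair get exactly 0.
    """
    if model is None:
        model = FoldingModel()
    codes = _encode(seq)
    n = codes.size
    if n == 0:
        raise ValueError("empty sequence")
    lookup = model.weight_matrix()
    # W[k, l]: weight of pair (k, l), zero unless l - k > min_hairpin.
    W = lookup[np.ix_(codes, codes)]
    spans = np.subtract.outer(np.arange(n), np.arange(n))  # spans[k,l] = k-l
    W[(-spans) <= model.min_hairpin] = 0.0

    # Inside pass.  E[i, j] = partition function over the half-open
    # interval [i, j); E[i, i] = 1 (empty), entries below the diagonal 0.
    E = np.zeros((n + 1, n + 1))
    np.fill_diagonal(E, 1.0)
    B = np.zeros((n, n))  # B[k, l]: structures on [k, l] with (k, l) paired
    for j in range(1, n + 1):
        l = j - 1
        # B[:, l] needs E[k+1, l], i.e. column l of E (length-(l-k-1) intervals).
        B[:l, l] = W[:l, l] * E[1 : l + 1, l]
        E[:j, j] = E[:j, j - 1] + E[:j, :j] @ B[:j, l]
    Z = float(E[0, n])

    # Outside pass over the same grammar.  Eout[i, j] is the summed weight of
    # contexts of the interval [i, j); Bout[k, l] that of contexts of the
    # closed pair span [k, l].
    Eout = np.zeros((n + 1, n + 1))
    Bout = np.zeros((n, n))
    Eout[0, n] = 1.0
    Bout[:, n - 1] = Eout[0, n] * E[0, : n].copy()[: n] if n >= 1 else 0.0
    # (B(k, n-1) appears as right child of the root span [0, n) with left
    # part [0, k); general columns are handled in the loop below.)
    for j in range(n - 1, -1, -1):
        col = Eout[:, j + 1].copy()  # rule [i, j+1) -> [i, j) + unpaired
        # rule: [i, J) -> [i, j) + B(j, J-1) for J > j
        col[: n + 1] += Eout[:, j + 1 :] @ B[j, j:n] if j < n else 0.0
        # rule: B(i-1, j) -> w * [i, j)
        col[1 : n + 1] += W[: n, j] * Bout[: n, j] if j < n else 0.0
        Eout[:, j] = col
        if j >= 1:
            # contexts of B(k, j-1), which sits as right child of [i, j)
            Bout[:, j - 1] = (Eout[: n + 1, j] @ E[: n + 1, : n])[: n]

    with np.errstate(invalid="ignore"):
        P = (B * Bout) / Z
    p_paired = P.sum(axis=1) + P.sum(axis=0)
    # Guard against floating accumulation slightly above 1.
    np.clip(p_paired, 0.0, 1.0, out=p_paired)
    return Z, p_paired


def fold_tir(
    genomes: Mapping[str, GenomeRecord],
    gene: GeneAnnotation,
    model: FoldingModel | None = None,
    upstream: int = 100,
    downstream: int = 100,
) -> PairingProfile:
    """Fold the start-codon-centered window (default offsets -100..+100).

    Windows truncated by a contig edge are folded as-is and flagged
    incomplete.  The window is genomic context, strand-aware, not clipped to
    transcript bounds.
    """
    window = extract_tir_window(genomes, gene, upstream, downstream)
    _, p = partition_function(window.sequence, model)
    return PairingProfile(
        gene_id=gene.gene_id,
        offset_start=window.offset_start,
        p_paired=p,
        complete=window.complete,
    )


def average_pairing_by_set(
    profiles_by_group: Mapping[object, Sequence[PairingProfile]],
    contrast: tuple[object, object] | None = None,
    alpha: float = 0.05,
):
    """Position-wise mean pairing probability per group, plus a group contrast.

    Returns (means, comparisons) as pandas DataFrames.  Means are taken over
    the genes informative at each offset.  If ``contrast`` names two groups,
    a per-position Welch t-test on per-gene probabilities is run with
    Bonferroni correction over the positions tested; positions where the
    test is degenerate (zero variance in one group only) get NaN p-values
    and are never flagged significant.
    """
    import pandas as pd

    if not profiles_by_group or any(
        len(v) == 0 for v in profiles_by_group.values()
    ):
        raise ValueError("every group must be nonempty")

    def collect(profiles: Sequence[PairingProfile]) -> dict[int, np.ndarray]:
        per_offset: dict[int, list[float]] = {}
        for prof in profiles:
            for off, p in zip(prof.offsets, prof.p_paired):
                per_offset.setdefault(off, []).append(float(p))
        return {k: np.array(v) for k, v in per_offset.items()}

    grouped = {g: collect(profs) for g, profs in profiles_by_group.items()}
    rows = []
    for g, per_offset in grouped.items():
        for off in sorted(per_offset):
            vals = per_offset[off]
            rows.append(
                {"group": g, "position": off, "mean_p": vals.mean(), "n": vals.size}
            )
    means = pd.DataFrame(rows)

    comparisons = None
    if contrast is not None:
        g1, g2 = contrast
        a, b = grouped[g1], grouped[g2]
        shared = sorted(set(a) & set(b))
        recs = []
        for off in shared:
            x, y = a[off], b[off]
            if x.size < 2 or y.size < 2:
                continue
            try:
                res = two_sample_t(x, y)
                stat, p = res.statistic, res.p_value
            except ZeroVarianceError:
                stat, p = np.nan, np.nan
            recs.append(
                {
                    "position": off,
                    "mean_p_1": x.mean(),
                    "mean_p_2": y.mean(),
                    "n1": x.size,
                    "n2": y.size,
                    "statistic": stat,
                    "p_value": p,
                }
            )
        comparisons = pd.DataFrame(recs)
        tested = comparisons["p_value"].notna()
        m = int(tested.sum())
        if m > 0:
            threshold, _ = bonferroni(
                comparisons.loc[tested, "p_value"].tolist(), alpha
            )
            comparisons["p_adjusted"] = np.minimum(comparisons["p_value"] * m, 1.0)
            comparisons["significant"] = comparisons["p_value"] < threshold
            comparisons.loc[~tested, "significant"] = False
            comparisons.attrs["bonferroni_m"] = m
            comparisons.attrs["threshold"] = threshold
    return means, comparisons
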