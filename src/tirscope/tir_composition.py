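"""Positional nucleotide-frequency profiles across TIRs and octile contrasts.

At each offset k, frequency(b, k) is the fraction of informative genes
(window covers k and the base is not N) carrying base b there.  Octile
contrasts compare per-gene 0/1 indicators between two gene groups with a
Welch t-test per position and Bonferroni correction over the positions
tested.  Genes are excluded position-wise, not gene-wise, when truncated or
ambiguous.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import TIRWindow
from .stats_core import ZeroVarianceError, bonferroni, two_sample_t

RNA_BASES = ("A", "C", "G", "U")

__all__ = [
    "positional_frequencies",
    "octile_contrast",
    "frequency_by_octile",
]


def _indicator(
    windows: Sequence[TIRWindow], position: int, nucleotide: str
) -> np.ndarray:
    """0/1 per informative gene: does the window carry `nucleotide` at `position`?"""
    vals = []
    for w in windows:
        base = w.base_at(position)
        if base is None or base == "N":
            continue
        vals.append(1.0 if base == nucleotide else 0.0)
    return np.array(vals)


def positional_frequencies(
    windows: Sequence[TIRWindow],
    positions: Iterable[int] = range(-30, 31),
) -> pd.DataFrame:
    """Per-position frequencies of A/C/G/U over a set of TIR windows.

    Returns a DataFrame indexed by position with columns A, C, G, U and n
    (number of informative genes at that position).  Frequencies at each
    position sum to 1 whenever n > 0.
    """
    if len(windows) == 0:
        raise ValueError("no windows given")
    rows = {}
    for pos in positions:
        counts = dict.fromkeys(RNA_BASES, 0)
        n = 0
        for w in windows:
            base = w.base_at(pos)
            if base is None or base == "N":
                continue
            counts[base] += 1
            n += 1
        freq = {b: (counts[b] / n if n else np.nan) for b in RNA_BASES}
        freq["n"] = n
        rows[pos] = freq
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "position"
    return out


def octile_contrast(
    windows_by_octile: Mapping[int, Sequence[TIRWindow]],
    positions: Iterable[int] = range(-30, 31),
    nucleotide: str = "A",
    octiles: tuple[int, int] = (1, 8),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-position frequency comparison between two octiles.

    The two-sample t-test runs on per-gene indicators; positions where both
    groups are constant and equal give p = 1, and positions degenerate in
    only one group get NaN p-values and are never flagged significant.
    Bonferroni correction uses m = number of positions with a defined test.
    """
    g1, g2 = octiles
    if g1 not in windows_by_octile or g2 not in windows_by_octile:
        raise ValueError(f"octiles {octiles} not both present")
    w1, w2 = windows_by_octile[g1], windows_by_octile[g2]
    if len(w1) == 0 or len(w2) == 0:
        raise ValueError("octile window sets must be nonempty")
    recs = []
    for pos in sorted(positions):
        x = _indicator(w1, pos, nucleotide)
        y = _indicator(w2, pos, nucleotide)
        if x.size < 2 or y.size < 2:
            continue
        try:
            res = two_sample_t(x, y)
            stat, p = res.statistic, res.p_value
        except ZeroVarianceError:
            stat, p = np.nan, np.nan
        recs.append(
            {
                "position": pos,
                "nucleotide": nucleotide,
                f"freq_octile{g1}": x.mean(),
                f"freq_octile{g2}": y.mean(),
                "n1": x.size,
                "n2": y.size,
                "statistic": stat,
                "p_value": p,
            }
        )
    out = pd.DataFrame(recs)
    tested = out["p_value"].notna()
    m = int(tested.sum())
    if m > 0:
        threshold, _ = bonferroni(out.loc[tested, "p_value"].tolist(), alpha)
        out["p_adjusted"] = np.minimum(out["p_value"] * m, 1.0)
        out["significant"] = out["p_value"] < threshold
        out.loc[~tested, "significant"] = False
        out.attrs["bonferroni_m"] = m
        out.attrs["threshold"] = threshold
    return out


def frequency_by_octile(
    windows_by_octile: Mapping[int, Sequence[TIRWindow]],
    position: int,
    nucleotide: str = "A",
) -> pd.Series:
    """Frequency of one base at one offset, per octile (trend-plot data)."""
    freqs = {}
    for octile in sorted(windows_by_octile):
        ind = _indicator(windows_by_octile[octile], position, nucleotide)
        freqs[octile] = float(ind.mean()) if ind.size else np.nan
    s = pd.Series(freqs, name=f"{nucleotide}@{position}")
    s.index.name = "octile"
    return s
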