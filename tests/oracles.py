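"""Independent oracles used by the tests.

The structure enumerator below brute-forces every nested secondary structure
of a short RNA and sums weights naively; it shares no code with the dynamic
program it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_partition(seq: str, model) -> tuple[float, np.ndarray]:
    """Exhaustively enumerate nested structures (n <= ~16) and sum weights."""
    n = len(seq)
    W = model.weight_matrix()
    order = {b: i for i, b in enumerate("ACGUN")}
    codes = [order[c] for c in seq]

    def w(i: int, j: int) -> float:
        return W[codes[i], codes[j]] if j - i > model.min_hairpin else 0.0

    def rec(i: int, j: int):
        """Yield every structure (tuple of pairs) over positions [i, j)."""
        if i >= j:
            yield ()
            return
        yield from rec(i + 1, j)  # i unpaired
        for l in range(i + 1, j):
            if w(i, l) > 0:
                for left in rec(i + 1, l):
                    for right in rec(l + 1, j):
                        yield ((i, l),) + left + right

    Z = 0.0
    paired_weight = np.zeros(n)
    for structure in rec(0, n):
        weight = 1.0
        for a, b in structure:
            weight *= w(a, b)
        Z += weight
        for a, b in structure:
            paired_weight[a] += weight
            paired_weight[b] += weight
    return Z, paired_weight / Z
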