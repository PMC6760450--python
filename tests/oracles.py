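"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — plain python loops over explicit
definitions — kept separate from the library code they check.
"""

from __future__ import annotations

import numpy as np


def brute_force_upgma(dist: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """UPGMA by direct evaluation of the definition.

    ``dist`` is a square symmetric matrix.  At every step the pair of
    clusters with the smallest average cross-pair distance (computed from
    the original matrix every time) is merged.  Returns the merge list as
    (members_i, members_j, height).
    """
    n = dist.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                pairs = [dist[i, j] for i in clusters[a] for j in clusters[b]]
                avg = sum(pairs) / len(pairs)
                if best is None or avg < best[0]:
                    best = (avg, a, b)
        avg, a, b = best
        merges.append((clusters[a], clusters[b], avg))
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def orbit_canonical(ops: np.ndarray, hkl: tuple[int, int, int]) -> tuple[int, int, int]:
    """Lexicographic maximum of the orbit {hkl · M}, one python max call."""
    h = np.asarray(hkl)
    return max(tuple(int(x) for x in h @ m) for m in ops)


def brute_force_unique(cell, ops: np.ndarray, centering_ok, d_of, d_min: float) -> set:
    """Unique reflections by exhaustive sphere scan and per-point orbit max."""
    import math

    bounds = [int(math.floor(length / d_min)) for length in (cell.a, cell.b, cell.c)]
    uniques = set()
    for h in range(-bounds[0], bounds[0] + 1):
        for k in range(-bounds[1], bounds[1] + 1):
            for l in range(-bounds[2], bounds[2] + 1):
                if (h, k, l) == (0, 0, 0):
                    continue
                if d_of((h, k, l)) < d_min - 1e-12:
                    continue
                if not centering_ok((h, k, l)):
                    continue
                uniques.add(orbit_canonical(ops, (h, k, l)))
    return uniques
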