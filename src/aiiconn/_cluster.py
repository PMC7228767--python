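"""Small internal helpers shared by connectome and spatial_stats."""
from __future__ import annotations

import math
from typing import Sequence


def single_linkage(points: Sequence[Sequence[float]], radius: float) -> list[int]:
    """Single-linkage clustering: indices i, j join if dist(i, j) <= radius.

    Returns a cluster label per point (labels are 0..k-1 in order of first
    appearance).  O(n^2); intended for per-cell synapse sets.
    """
    n = len(points)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if math.dist(points[i], points[j]) <= radius:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri

    labels: dict[int, int] = {}
    out: list[int] = []
    for i in range(n):
        r = find(i)
        if r not in labels:
            labels[r] = len(labels)
        out.append(labels[r])
    return out
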