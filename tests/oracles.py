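"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately written as plain Python loops over pixels or
explicit enumerations, sharing no code path with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np

SQRT2 = math.sqrt(2.0)

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def brute_max_project(stack):
    stack = np.asarray(stack)
    out = np.empty(stack.shape[1:], dtype=stack.dtype)
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            out[r, c] = max(stack[k, r, c] for k in range(stack.shape[0]))
    return out


def brute_dilate(mask, iterations):
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    for _ in range(iterations):
        out = mask.copy()
        for r in range(h):
            for c in range(w):
                if mask[r, c]:
                    continue
                for dr, dc in _NEIGHBORS8:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                        out[r, c] = True
                        break
        mask = out
    return mask


def _flood_components(mask):
    """8-connected components by explicit BFS; returns label array, count."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    labels = np.zeros((h, w), dtype=int)
    current = 0
    for r0 in range(h):
        for c0 in range(w):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            current += 1
            queue = [(r0, c0)]
            labels[r0, c0] = current
            while queue:
                r, c = queue.pop()
                for dr, dc in _NEIGHBORS8:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not labels[rr, cc]:
                        labels[rr, cc] = current
                        queue.append((rr, cc))
    return labels, current


def pixel_graph_lengths(skeleton, source_mask, pixel_size_um=1.0):
    """Per-focus skeleton lengths by pairwise pixel-graph traversal.

    Every unordered 8-adjacent skeleton pixel pair is an edge (orthogonal 1,
    diagonal sqrt(2)); a diagonal edge is skipped when either of its two
    orthogonal corner pixels is skeleton (it would re-count a two-step
    orthogonal link).  Edges accumulate into the 8-connected component of
    the source mask.  Returns the sorted list of per-component lengths (um).
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    labels, n = _flood_components(source_mask)
    totals = {i: 0.0 for i in range(1, n + 1)}
    h, w = skeleton.shape
    pixels = [(r, c) for r in range(h) for c in range(w) if skeleton[r, c]]

    def is_skel(r, c):
        return 0 <= r < h and 0 <= c < w and skeleton[r, c]

    for r, c in pixels:
        for dr, dc in [(0, 1), (1, -1), (1, 0), (1, 1)]:  # each pair once
            rr, cc = r + dr, c + dc
            if not is_skel(rr, cc):
                continue
            if dr and dc:  # diagonal: chord rule
                if is_skel(r, c + dc) or is_skel(r + dr, c):
                    continue
                weight = SQRT2
            else:
                weight = 1.0
            totals[labels[r, c]] += weight
    return sorted(v * pixel_size_um for v in totals.values())


def mwu_exact_two_tailed(a, b):
    """Exact two-tailed Mann-Whitney p by full enumeration of rank splits."""
    a = list(map(float, a))
    b = list(map(float, b))
    combined = sorted(a + b)
    assert len(set(combined)) == len(combined), "oracle requires tie-free data"
    n1, n2 = len(a), len(b)

    def u1_of(indices_a):
        # U1 = number of (x in A, y in B) pairs with x > y
        set_a = set(indices_a)
        u = 0
        for i in set_a:
            u += sum(1 for j in range(n1 + n2) if j not in set_a and i > j)
        return u

    observed_u1 = sum(1 for x in a for y in b if x > y)
    us = [u1_of(comb) for comb in combinations(range(n1 + n2), n1)]
    total = len(us)
    p_le = sum(1 for u in us if u <= observed_u1) / total
    p_ge = sum(1 for u in us if u >= observed_u1) / total
    return min(1.0, 2.0 * min(p_le, p_ge))
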