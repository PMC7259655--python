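"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (full
enumeration, textbook formulas) without sharing code paths with the
package implementation they check.
"""

from __future__ import annotations

import numpy as np

HEPTAMER = "CACAGTG"
NONAMER = "ACAAAAACC"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def brute_force_rss(seq, anchor, spacer_class, window, orientation="downstream",
                    tolerance=1, min_hept=5, min_non=6):
    """Enumerate every (heptamer position, spacer) arrangement and score it.

    Returns (heptamer_start, spacer, hept_score, non_score) of the best
    passing arrangement under the same preference order as the detector
    (score, proximity to anchor, spacer closeness, shorter spacer), or None.
    """
    results = []
    spacers = range(spacer_class - tolerance, spacer_class + tolerance + 1)
    if orientation == "downstream":
        for h in range(anchor, min(anchor + window, len(seq))):
            hept = seq[h:h + 7]
            if len(hept) < 7 or not hept.startswith("CAC"):
                continue
            hs = sum(a == b for a, b in zip(hept, HEPTAMER))
            for sp in spacers:
                non = seq[h + 7 + sp:h + 16 + sp]
                if len(non) < 9:
                    continue
                ns = sum(a == b for a, b in zip(non, NONAMER))
                if hs >= min_hept and ns >= min_non:
                    results.append(((-(hs + ns), h - anchor,
                                     abs(sp - spacer_class), sp),
                                    (h, sp, hs, ns)))
    else:
        for e in range(anchor, max(anchor - window, 0) - 1, -1):
            h0 = e - 7
            if h0 < 0:
                continue
            hept = rc(seq[h0:e])
            if not hept.startswith("CAC"):
                continue
            hs = sum(a == b for a, b in zip(hept, HEPTAMER))
            for sp in spacers:
                n0 = h0 - sp - 9
                if n0 < 0:
                    continue
                non = rc(seq[n0:n0 + 9])
                ns = sum(a == b for a, b in zip(non, NONAMER))
                if hs >= min_hept and ns >= min_non:
                    results.append(((-(hs + ns), anchor - e,
                                     abs(sp - spacer_class), sp),
                                    (h0, sp, hs, ns)))
    if not results:
        return None
    return min(results)[1]


def brute_force_nj(labels, d):
    """Textbook neighbour joining, re-derived; returns (splits, lengths).

    splits: set of frozensets (side not containing the first sorted label)
    for internal edges; lengths: sorted list of all branch lengths
    (negative estimates clamped at zero).
    """
    labels = list(labels)
    ref = min(labels)
    d = {a: {b: float(d[i][j]) for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    groups = {lab: frozenset([lab]) for lab in labels}
    active = list(labels)
    splits = set()
    lengths = []

    def clamp(x):
        return max(x, 0.0)

    def canonical(side):
        full = frozenset().union(*groups.values()) if False else None
        all_labs = set(labels)
        side = frozenset(side)
        return frozenset(all_labs - side) if ref in side else side

    k = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[a][b] - r[a] - r[b]
                key = (q, tuple(sorted((a, b))))
                if best is None or key < best:
                    best = key
                    pair = (a, b)
        a, b = pair
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lengths += [clamp(la), clamp(d[a][b] - la)]
        new = f"@{k}"
        k += 1
        groups[new] = groups.pop(a) | groups.pop(b)
        if 1 < len(groups[new]) < len(labels) - 1:
            splits.add(canonical(groups[new]))
        d[new] = {}
        for c in active:
            if c in (a, b):
                continue
            d[new][c] = d[c][new] = 0.5 * (d[a][c] + d[b][c] - d[a][b])
        active = [c for c in active if c not in (a, b)] + [new]
    a, b, c = sorted(active)
    lengths += [clamp(0.5 * (d[a][b] + d[a][c] - d[b][c])),
                clamp(0.5 * (d[a][b] + d[b][c] - d[a][c])),
                clamp(0.5 * (d[a][c] + d[b][c] - d[a][b]))]
    for g in (groups[a], groups[b], groups[c]):
        if 1 < len(g) < len(labels) - 1:
            splits.add(canonical(g))
    return splits, sorted(lengths)


def additive_matrix_4taxon(inner=1.0, tips=(1.0, 2.0, 3.0, 4.0)):
    """Distances for the tree ((A,B),(C,D)) with given branch lengths."""
    a, b, c, d = tips
    m = np.array([
        [0, a + b, a + inner + c, a + inner + d],
        [a + b, 0, b + inner + c, b + inner + d],
        [a + inner + c, b + inner + c, 0, c + d],
        [a + inner + d, b + inner + d, c + d, 0],
    ], dtype=float)
    return ["A", "B", "C", "D"], m
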