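"""Jukes-Cantor distances, neighbour-joining trees, bootstrap consensus
and clan assignment for V gene segments.

The Jukes-Cantor model corrects an observed proportion of differing sites
p into an expected number of substitutions per site,
``d = -(3/4) ln(1 - (4/3) p)``; it saturates at p = 3/4.  Trees are built
with the Saitou-Nei neighbour-joining agglomeration, unrooted, with
deterministic tie-breaking, and clan membership is read off a joint tree
of query segments and clan-labelled exemplars by patristic distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

JC_SATURATION = 0.75
#: finite stand-in distance for saturated pairs when capping is requested
JC_CAP = 5.0


class SaturationError(ValueError):
    """Observed divergence at or beyond the Jukes-Cantor domain boundary."""


def jc_distance(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance between two aligned, equal-length sequences.

    Columns containing a gap ('-' or '.') in either sequence are removed
    pairwise before computing the mismatch proportion.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    n = mismatches = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in "-." or b in "-.":
            continue
        n += 1
        if a != b:
            mismatches += 1
    if n == 0:
        raise ValueError("no comparable (gap-free) columns")
    p = mismatches / n
    return jc_from_p(p)


def jc_from_p(p: float) -> float:
    if p >= JC_SATURATION:
        raise SaturationError(f"mismatch proportion {p:.3f} >= 0.75 saturates "
                              "the Jukes-Cantor correction")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix must be finite")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be nonnegative")

    @classmethod
    def from_alignment(cls, alignment: dict[str, str],
                       on_saturation: str = "error") -> "DistanceMatrix":
        """Pairwise Jukes-Cantor distances over an MSA (pairwise deletion).

        ``on_saturation="cap"`` replaces saturated pairs (p >= 0.75) with a
        large finite ceiling instead of raising; used during bootstrap where
        resampling can push divergent pairs past the JC domain.
        """
        labels = list(alignment)
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                try:
                    dij = jc_distance(alignment[labels[i]],
                                      alignment[labels[j]])
                except SaturationError:
                    if on_saturation != "cap":
                        raise
                    dij = JC_CAP
                d[i, j] = d[j, i] = dij
        return cls(labels, d)

    def to_phylip(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.d):
                fh.write(lab + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


@dataclass
class CladeTree:
    """An unrooted tree with branch lengths and optional bootstrap support.

    ``support`` maps canonical bipartitions (frozenset of the side not
    containing the alphabetically first label) to replicate fractions.
    """

    tree: dendropy.Tree
    support: dict[frozenset, float] | None = None
    negative_branches_clamped: int = 0
    labels: list[str] = field(default_factory=list)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def bipartitions(self) -> set[frozenset]:
        return tree_bipartitions(self.tree, self.labels)

    def patristic(self) -> dict[tuple[str, str], float]:
        pdm = self.tree.phylogenetic_distance_matrix()
        tns = self.tree.taxon_namespace
        out = {}
        for i, a in enumerate(self.labels):
            for b in self.labels[i + 1:]:
                dist = pdm.patristic_distance(tns.get_taxon(a), tns.get_taxon(b))
                out[(a, b)] = out[(b, a)] = dist
        return out


def canonical_split(side: set[str] | frozenset, labels: list[str]) -> frozenset:
    """Represent a bipartition by the side not containing the first label."""
    ref = min(labels)
    side = frozenset(side)
    return frozenset(set(labels) - side) if ref in side else side


def tree_bipartitions(tree: dendropy.Tree, labels: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions of an (un)rooted dendropy tree."""
    out = set()
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        leaves = {lf.taxon.label for lf in node.leaf_iter()}
        if 1 < len(leaves) < len(labels) - 1:
            out.add(canonical_split(leaves, labels))
    return out


def nj_tree(dm: DistanceMatrix) -> CladeTree:
    """Saitou-Nei neighbour joining; unrooted, deterministic.

    Ties in the Q criterion are broken toward the lexicographically lowest
    (sorted) label pair; negative branch-length estimates are clamped to 0
    and counted in ``negative_branches_clamped``.
    """
    labels = list(dm.labels)
    if len(labels) < 3:
        raise ValueError("neighbour joining requires >= 3 labels")
    d = {a: {b: dm.d[i, j] for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    tns = dendropy.TaxonNamespace(labels)
    nodes = {lab: dendropy.Node(taxon=tns.get_taxon(lab)) for lab in labels}
    active = list(labels)
    clamped = 0
    counter = 0

    def _clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[a][b] for b in active if b != a) for a in active}
        best_pair = None
        best_q = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                q = (n - 2) * d[a][b] - r[a] - r[b]
                key = tuple(sorted((a, b)))
                if best_q is None or q < best_q - 1e-12 or \
                        (abs(q - best_q) <= 1e-12 and key < best_pair):
                    best_q, best_pair = q, key
        a, b = best_pair
        la = 0.5 * d[a][b] + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[a][b] - la
        new_label = f"__nj{counter}"
        counter += 1
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        na.edge.length = _clamp(la)
        nb.edge.length = _clamp(lb)
        parent.add_child(na)
        parent.add_child(nb)
        nodes[new_label] = parent
        d[new_label] = {}
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
            d[new_label][c] = d[c][new_label] = duc
        active = [c for c in active if c not in (a, b)] + [new_label]

    a, b, c = sorted(active)
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    root = dendropy.Node()
    for lab, ln in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(lab)
        node.edge.length = _clamp(ln)
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return CladeTree(tree=tree, negative_branches_clamped=clamped, labels=labels)


# --------------------------------------------------------------------------
# bootstrap


def _resample_columns(alignment: dict[str, str], rng) -> dict[str, str]:
    ncol = len(next(iter(alignment.values())))
    idx = rng.integers(0, ncol, size=ncol)
    return {k: "".join(v[i] for i in idx) for k, v in alignment.items()}


def majority_rule_consensus(split_freqs: dict[frozenset, float],
                            labels: list[str]) -> dendropy.Tree:
    """Build the majority-rule (>0.5) consensus tree from split frequencies."""
    majority = sorted((s for s, f in split_freqs.items() if f > 0.5),
                      key=lambda s: (-len(s), sorted(s)))
    # nest compatible majority splits from largest to smallest
    children: dict = {None: [frozenset([lab]) for lab in labels]}
    tns = dendropy.TaxonNamespace(labels)
    root = dendropy.Node()
    dnodes = {None: root}
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        root.add_child(node)
        dnodes[frozenset([lab])] = node

    def leafset(group_key) -> frozenset:
        if group_key is None:
            return frozenset(labels)
        return group_key

    for split in majority:
        # find deepest node whose leafset contains the split
        def descend(key):
            node_children = children.get(key, [])
            for ck in node_children:
                if split <= leafset(ck) and len(ck) > len(split):
                    return descend(ck)
            return key
        host = descend(None)
        host_children = children.get(host, [])
        grouped = [ck for ck in host_children if leafset(ck) <= split]
        if not grouped or frozenset().union(*[leafset(g) for g in grouped]) != split:
            continue  # incompatible with already-placed splits (ties at 0.5)
        new_node = dendropy.Node()
        for g in grouped:
            dnodes[g].parent_node.remove_child(dnodes[g])
            new_node.add_child(dnodes[g])
        dnodes[host].add_child(new_node)
        children[host] = [ck for ck in host_children if ck not in grouped] + [split]
        children[split] = grouped
        dnodes[split] = new_node
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return tree


def bootstrap_consensus(alignment: dict[str, str], n_reps: int,
                        seed: int = 0) -> CladeTree:
    """Column-resampled NJ bootstrap with majority-rule consensus.

    Support values are the fraction of replicates containing each
    bipartition, reported for every split in the consensus.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    ncol = len(next(iter(alignment.values())))
    if ncol < 2:
        raise ValueError("alignment must have at least 2 columns")
    labels = list(alignment)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        rep = _resample_columns(alignment, rng)
        dm = DistanceMatrix.from_alignment(rep, on_saturation="cap")
        t = nj_tree(dm)
        for split in t.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    freqs = {s: c / n_reps for s, c in counts.items()}
    tree = majority_rule_consensus(freqs, labels)
    support = {s: freqs[s] for s in tree_bipartitions(tree, labels)
               if s in freqs}
    return CladeTree(tree=tree, support=support, labels=labels)


# --------------------------------------------------------------------------
# clan assignment


def _pairwise_p(seq_a: str, seq_b: str) -> float:
    """Mismatch proportion over aligned columns of a global alignment."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aln = aligner.align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    n = mm = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for x, y in zip(seq_a[a0:a1], seq_b[b0:b1]):
            n += 1
            if x != y:
                mm += 1
    if n == 0:
        raise SaturationError("no aligned columns")
    return mm / n


def assign_clan(
    v_segments: dict[str, str],
    exemplars: dict[str, str],
    clans: dict[str, str],
) -> dict[str, str | None]:
    """Assign each V segment the clan of its nearest exemplar.

    A joint NJ tree is built over segments plus exemplars from pairwise
    Jukes-Cantor distances (global alignment, pairwise deletion); each
    segment takes the clan of the exemplar at smallest patristic distance.
    Exact patristic ties are resolved by smaller JC distance; residual ties
    and unalignable segments are left unassigned (None).
    """
    import logging
    log = logging.getLogger(__name__)
    if set(clans) != set(exemplars):
        raise ValueError("clans must label exactly the exemplar set")
    names = list(v_segments) + [e for e in exemplars if e not in v_segments]
    seqs = {**exemplars, **v_segments}
    n = len(names)
    jc = np.zeros((n, n))
    ok = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                jc[i, j] = jc[j, i] = jc_from_p(
                    _pairwise_p(seqs[names[i]], seqs[names[j]]))
            except SaturationError:
                jc[i, j] = jc[j, i] = np.nan
    result: dict[str, str | None] = {}
    # segments that cannot be aligned to any exemplar are unassigned
    exemplar_idx = [names.index(e) for e in exemplars]
    usable = []
    for i, name in enumerate(names):
        if name in v_segments and np.isnan(jc[i, exemplar_idx]).all():
            log.warning("segment %s unalignable to every exemplar", name)
            result[name] = None
            ok[i] = False
        else:
            usable.append(i)
    sub = jc[np.ix_(usable, usable)]
    sub = np.nan_to_num(sub, nan=np.nanmax(sub[np.isfinite(sub)]) * 2 + 1.0
                        if np.isfinite(sub).any() else 10.0)
    sub_names = [names[i] for i in usable]
    dm = DistanceMatrix(sub_names, sub)
    tree = nj_tree(dm)
    pat = tree.patristic()
    for name in v_segments:
        if name in result:
            continue
        if name in exemplars:
            result[name] = clans[name]
            continue
        scored = []
        for ex in exemplars:
            if ex not in sub_names:
                continue
            i, j = names.index(name), names.index(ex)
            scored.append((pat[(name, ex)], ex))
        scored.sort()
        best_d = scored[0][0]
        nearest = [ex for p, ex in scored if abs(p - best_d) <= 1e-9]
        if len(nearest) == 1:
            result[name] = clans[nearest[0]]
            continue
        # patristic tie: fall back to JC distance
        i = names.index(name)
        jc_scored = sorted((jc[i, names.index(ex)], ex) for ex in nearest)
        if len(jc_scored) > 1 and abs(jc_scored[0][0] - jc_scored[1][0]) <= 1e-12:
            result[name] = None  # irresolvable tie
        else:
            result[name] = clans[jc_scored[0][1]]
    return result
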