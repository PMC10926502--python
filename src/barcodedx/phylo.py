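"""Tamura–Nei distances, neighbor joining, jackknife support, clade reports.

The distance model is TN93 (Tamura & Nei 1993), which separates the two
transition classes (A<->G at proportion P1, C<->T at P2) from transversions
(Q) and allows unequal base frequencies:

    d = -2(pA pG / pR) ln(1 - pR P1/(2 pA pG) - Q/(2 pR))
        -2(pC pT / pY) ln(1 - pY P2/(2 pC pT) - Q/(2 pY))
        -2(pR pY - pA pG pY/pR - pC pT pR/pY) ln(1 - Q/(2 pR pY))

with pR = pA + pG, pY = pC + pT.  Any non-positive log argument means the
pair is saturated and the distance is flagged rather than reported.

Trees are unrooted, held as networkx graphs with branch lengths on edges;
support values from delete-half jackknifing of alignment columns annotate the
internal edges of the full-data tree as bipartition recovery percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .alignment import Alignment, SampleTable, UNAMBIGUOUS
from .errors import DistanceError, MetadataError

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(aln: Alignment) -> np.ndarray:
    """Rows as int8: A,C,G,T -> 0..3; gaps/ambiguity -> -1 (excluded pairwise)."""
    arr = np.full((aln.n, aln.L), -1, dtype=np.int8)
    for i, row in enumerate(aln.rows):
        for j, ch in enumerate(row):
            if ch in UNAMBIGUOUS:
                arr[i, j] = _BASE_INDEX[ch]
    return arr


@dataclass
class TN93Components:
    pi: np.ndarray          # empirical A,C,G,T frequencies for the pair
    P1: float               # A<->G difference proportion
    P2: float               # C<->T difference proportion
    Q: float                # transversion proportion
    comparable: int         # number of sites compared
    d: float                # distance (nan when saturated)
    saturated: bool


def tn93_pair(seq_i: np.ndarray, seq_j: np.ndarray, freqs: np.ndarray | None = None) -> TN93Components:
    """TN93 distance between two encoded rows using pairwise deletion.

    ``freqs`` overrides the empirical base frequencies (used for
    alignment-wide pooling); by default frequencies are pooled over the two
    sequences at their comparable sites.
    """
    mask = (seq_i >= 0) & (seq_j >= 0)
    m = int(mask.sum())
    if m == 0:
        raise DistanceError("no comparable (unambiguous, non-gap) sites for pair")
    a, b = seq_i[mask], seq_j[mask]
    if freqs is None:
        counts = np.bincount(np.concatenate([a, b]), minlength=4).astype(float)
        pi = counts / counts.sum()
    else:
        pi = np.asarray(freqs, dtype=float)
    diff = a != b
    ag = int(np.sum(diff & np.isin(a, [0, 2]) & np.isin(b, [0, 2])))
    ct = int(np.sum(diff & np.isin(a, [1, 3]) & np.isin(b, [1, 3])))
    tv = int(diff.sum()) - ag - ct
    P1, P2, Q = ag / m, ct / m, tv / m
    pA, pC, pG, pT = pi
    pR, pY = pA + pG, pC + pT
    d = 0.0
    saturated = False

    def _term(coef: float, arg: float) -> float:
        nonlocal saturated
        if coef == 0.0:
            return 0.0
        if arg <= 0.0:
            saturated = True
            return math.nan
        return -coef * math.log(arg)

    k1 = 2.0 * pA * pG / pR if pR > 0 else 0.0
    k2 = 2.0 * pC * pT / pY if pY > 0 else 0.0
    if k1 > 0:
        d += _term(k1, 1.0 - P1 * pR / (2.0 * pA * pG) - Q / (2.0 * pR))
    elif P1 > 0:
        saturated = True
    if k2 > 0:
        d += _term(k2, 1.0 - P2 * pY / (2.0 * pC * pT) - Q / (2.0 * pY))
    elif P2 > 0:
        saturated = True
    k3 = 2.0 * (pR * pY - (pA * pG * pY / pR if pR > 0 else 0.0) - (pC * pT * pR / pY if pY > 0 else 0.0))
    if pR > 0 and pY > 0:
        d += _term(k3, 1.0 - Q / (2.0 * pR * pY))
    elif Q > 0:
        saturated = True
    if saturated or math.isnan(d):
        return TN93Components(pi, P1, P2, Q, m, math.nan, True)
    return TN93Components(pi, P1, P2, Q, m, max(d, 0.0), False)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.saturated = np.asarray(self.saturated, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.labels)

    def any_saturated(self) -> bool:
        return bool(self.saturated.any())


def tn93_distance(aln: Alignment, pair_deletion: bool = True, freq_mode: str = "pair") -> DistanceMatrix:
    """All-pairs TN93 matrix.

    ``freq_mode='pair'`` pools empirical base frequencies per pair (default);
    ``'alignment'`` pools once over every unambiguous call in the alignment.
    With ``pair_deletion=False`` only columns unambiguous in *every* row are
    used for all pairs (complete deletion).
    """
    if aln.n < 2:
        raise DistanceError("need at least two sequences")
    enc = _encode(aln)
    if not pair_deletion:
        keep = (enc >= 0).all(axis=0)
        if not keep.any():
            raise DistanceError("complete deletion leaves no comparable columns")
        enc = enc[:, keep]
    freqs = None
    if freq_mode == "alignment":
        counts = np.bincount(enc[enc >= 0], minlength=4).astype(float)
        freqs = counts / counts.sum()
    elif freq_mode != "pair":
        raise ValueError(f"unknown freq_mode {freq_mode!r}")
    n = aln.n
    D = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                comp = tn93_pair(enc[i], enc[j], freqs=freqs)
            except DistanceError as exc:
                raise DistanceError(
                    f"pair ({aln.sample_ids[i]}, {aln.sample_ids[j]}): {exc}"
                ) from None
            if comp.saturated:
                sat[i, j] = sat[j, i] = True
                D[i, j] = D[j, i] = math.nan
            else:
                D[i, j] = D[j, i] = comp.d
    return DistanceMatrix(list(aln.sample_ids), D, sat)


def jc69_distance(p: float) -> float:
    """Jukes–Cantor distance from a raw difference proportion (reference model)."""
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return math.nan
    return -0.75 * math.log(arg)


# --- neighbor joining --------------------------------------------------------

@dataclass
class PhyloTree:
    """Unrooted tree: leaves are label strings, internal nodes integers.

    Edge attributes: ``length`` (>= 0) and, after jackknifing, ``support``
    (percentage, internal edges only).
    """

    graph: nx.Graph
    leaves: list[str]
    outgroup: str | None = None

    def internal_edges(self) -> list[tuple]:
        return [
            (u, v) for u, v in self.graph.edges
            if self.graph.degree(u) > 1 and self.graph.degree(v) > 1
        ]

    def bipartitions(self) -> dict[frozenset, tuple]:
        """Map each internal edge to its leaf-set side not containing leaves[0]."""
        ref = self.leaves[0]
        out = {}
        for u, v in self.internal_edges():
            g = self.graph.copy()
            g.remove_edge(u, v)
            side_u = {x for x in nx.node_connected_component(g, u) if isinstance(x, str)}
            side = side_u if ref not in side_u else set(self.leaves) - side_u
            if 1 < len(side) < len(self.leaves) - 1 or (len(side) in (1, len(self.leaves) - 1)):
                out[frozenset(side)] = (u, v)
        return out

    def path_length_matrix(self) -> np.ndarray:
        lengths = dict(nx.all_pairs_dijkstra_path_length(self.graph, weight="length"))
        n = len(self.leaves)
        M = np.zeros((n, n))
        for i, a in enumerate(self.leaves):
            for j, b in enumerate(self.leaves):
                M[i, j] = lengths[a][b]
        return M

    def newick(self, root: str | None = None) -> str:
        """Serialize; rooted at the given leaf's attachment (default: outgroup or first leaf)."""
        root_leaf = root or self.outgroup or self.leaves[0]
        g = self.graph
        anchor = next(iter(g.neighbors(root_leaf)))

        def fmt_support(u, v):
            s = g.edges[u, v].get("support")
            return "" if s is None else f"{s:g}"

        def rec(node, parent):
            children = [x for x in g.neighbors(node) if x != parent]
            if not children:
                return f"{node}:{g.edges[node, parent]['length']:.6f}"
            inner = ",".join(rec(c, node) for c in children)
            if parent is None:
                return f"({inner})"
            return f"({inner}){fmt_support(node, parent)}:{g.edges[node, parent]['length']:.6f}"

        others = [x for x in g.neighbors(anchor) if x != root_leaf]
        inner = ",".join(rec(c, anchor) for c in others)
        return f"({root_leaf}:{g.edges[root_leaf, anchor]['length']:.6f},{inner});"


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with a deterministic tie rule.

    Ties in the Q-criterion are broken by the lowest (i, j) original-label
    index pair.  Negative branch lengths are clamped to zero with the deficit
    moved onto the sister branch, so reported lengths are nonnegative while
    path lengths through the join are preserved.
    """
    if D.n < 3:
        raise DistanceError("neighbor joining needs at least 3 labels")
    if D.any_saturated():
        bad = [
            (D.labels[i], D.labels[j])
            for i in range(D.n) for j in range(i + 1, D.n) if D.saturated[i, j]
        ]
        raise DistanceError(
            f"saturated distances present {bad[:5]}; exclude those sequences first"
        )
    g = nx.Graph()
    active: list[tuple[int, object]] = [(i, lab) for i, lab in enumerate(D.labels)]
    dist: dict[tuple, float] = {}
    for i in range(D.n):
        for j in range(i + 1, D.n):
            dist[frozenset((D.labels[i], D.labels[j]))] = float(D.matrix[i, j])

    def d(a, b):
        return dist[frozenset((a, b))]

    next_internal = 0
    while len(active) > 2:
        r = len(active)
        totals = {node: sum(d(node, other) for _, other in active if other != node) for _, node in active}
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                (oi, a), (oj, b) = active[ii], active[jj]
                q = (r - 2) * d(a, b) - totals[a] - totals[b]
                key = (q, oi, oj)
                if best is None or key < best[0]:
                    best = (key, ii, jj)
        _, ii, jj = best
        (oi, a), (oj, b) = active[ii], active[jj]
        dab = d(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2.0 * (r - 2))
        lb = dab - la
        # clamp negatives, moving the deficit to the sister branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        la, lb = max(la, 0.0), max(lb, 0.0)
        u = ("I", next_internal)
        next_internal += 1
        g.add_edge(a, u, length=la)
        g.add_edge(b, u, length=lb)
        new_active = [(o, n_) for o, n_ in active if n_ not in (a, b)]
        for _, c in new_active:
            dist[frozenset((u, c))] = 0.5 * (d(a, c) + d(b, c) - dab)
        active = new_active + [(min(oi, oj), u)]
        active.sort(key=lambda t: t[0])
    (_, a), (_, b) = active
    g.add_edge(a, b, length=max(d(a, b), 0.0))
    return PhyloTree(g, list(D.labels))


def jackknife_support(
    aln: Alignment,
    replicates: int = 1000,
    deletion: float = 0.5,
    seed: int = 0,
    outgroup: str | None = None,
    freq_mode: str = "pair",
) -> PhyloTree:
    """Delete-``deletion`` column jackknife support on the full-data NJ tree.

    Each replicate removes ceil(deletion*L) columns without replacement,
    recomputes TN93 + NJ, and internal edges of the full tree are annotated
    with the percentage of successful replicates recovering their bipartition.
    Replicates whose subsampled matrix is saturated or degenerate are skipped
    and excluded from the denominator.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not (0 < deletion < 1):
        raise ValueError("deletion fraction must lie in (0, 1)")
    full = neighbor_joining(tn93_distance(aln, freq_mode=freq_mode))
    full.outgroup = outgroup
    target_bips = full.bipartitions()
    hits = {bip: 0 for bip in target_bips}
    rng = np.random.default_rng(seed)
    n_drop = math.ceil(deletion * aln.L)
    successes = 0
    for _ in range(replicates):
        drop = set(rng.choice(aln.L, size=n_drop, replace=False).tolist())
        keep = [j for j in range(aln.L) if j not in drop]
        sub = Alignment(list(aln.sample_ids), ["".join(r[j] for j in keep) for r in aln.rows])
        try:
            t = neighbor_joining(tn93_distance(sub, freq_mode=freq_mode))
        except DistanceError:
            continue
        successes += 1
        rep_bips = set(t.bipartitions().keys())
        for bip in hits:
            if bip in rep_bips:
                hits[bip] += 1
    denom = max(successes, 1)
    for bip, edge in target_bips.items():
        full.graph.edges[edge]["support"] = round(100.0 * hits[bip] / denom, 1)
    return full


# --- clade composition -------------------------------------------------------

def clade_composition(tree: PhyloTree, table: SampleTable, label_field: str = "species") -> dict:
    """Per-clade label percentages and per-label monophyly on the unrooted tree.

    A label is monophyletic when its leaf set equals one side of some
    bipartition (the side away from the declared outgroup when one is set);
    singleton labels are trivially monophyletic.
    """
    labels = {}
    for leaf in tree.leaves:
        if leaf not in table:
            raise MetadataError(f"unlabeled leaf {leaf!r}")
        labels[leaf] = table.label_of(leaf, label_field)
    bips = tree.bipartitions()
    sides = set()
    for side in bips:
        sides.add(side)
        sides.add(frozenset(set(tree.leaves) - side))
    clades = []
    for side, edge in bips.items():
        use = side
        if tree.outgroup is not None and tree.outgroup in side:
            use = frozenset(set(tree.leaves) - side)
        tally = {}
        for leaf in use:
            tally[labels[leaf]] = tally.get(labels[leaf], 0) + 1
        total = len(use)
        clades.append(
            {
                "edge": edge,
                "size": total,
                "composition": {lab: 100.0 * c / total for lab, c in sorted(tally.items())},
            }
        )
    mono = {}
    for lab in sorted(set(labels.values())):
        members = frozenset(l for l, v in labels.items() if v == lab)
        mono[lab] = len(members) == 1 or members in sides or members == frozenset(tree.leaves)
    return {"clades": clades, "monophyly": mono}
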