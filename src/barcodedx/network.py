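"""Statistical-parsimony (TCS-style) haplotype networks and step metrics.

Haplotypes are joined in nondecreasing order of their mutational step count,
never closing a cycle, up to the parsimony connection limit: the largest step
count whose probability of a strictly parsimonious history still meets the
confidence level (0.95 by default).  Connections longer than a single step are
drawn through abstract, unsampled intermediate nodes so that every edge in the
final graph represents exactly one mutational step ("hatch mark").

The parsimony probability is computed from the generative model underlying
statistical parsimony: mutations strike sites uniformly at random along a
sequence of L comparable sites, each changing the base to one of the three
alternatives.  The number of visibly different sites D then follows a simple
Markov chain in the number of mutations M:

    D -> D+1 with prob (L-D)/L          (a so-far-identical site is hit)
    D -> D-1 with prob (D/L) * 1/3      (a differing site reverts)
    D -> D   with prob (D/L) * 2/3      (a differing site changes again)

The probability that j observed differences arose from exactly j mutations
(no superimposed or parallel changes) is P(M=j | D=j) under a flat prior over
M, truncated where the terms become numerically negligible.  It decreases in
j and increases in L, and the connection limit is the largest j keeping it at
or above the confidence level.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .alignment import HaplotypeSet, UNAMBIGUOUS
from .errors import NetworkError


def pairwise_steps(haps: HaplotypeSet) -> np.ndarray:
    """Hamming step matrix over haplotypes, counting only columns where both
    calls are unambiguous bases (gaps and IUPAC ambiguity excluded pairwise)."""
    seqs = haps.sequences
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise NetworkError(f"haplotypes have unequal lengths: {sorted(lengths)}")
    n = len(seqs)
    M = np.zeros((n, n), dtype=int)
    plain = [np.frombuffer(s.encode(), dtype="S1") for s in seqs]
    ok = [np.isin(p, [b"A", b"C", b"G", b"T"]) for p in plain]
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            M[i, j] = M[j, i] = int(np.sum((plain[i] != plain[j]) & both))
    return M


@dataclass
class ParsimonyLimit:
    L: int
    alpha: float
    max_steps: int


def _prob_diff_given_mutations(L: int, j: int, max_extra: int) -> np.ndarray:
    """P(D = j | M) for M = j .. j+max_extra via the site-hit Markov chain."""
    probs = np.zeros(max_extra + 1)
    # distribution over D after M events; start at M=0, D=0
    dist = np.zeros(min(L, j + max_extra) + 2)
    dist[0] = 1.0
    dmax = len(dist) - 1
    for m in range(1, j + max_extra + 1):
        new = np.zeros_like(dist)
        for dd in range(dmax + 1):
            p = dist[dd]
            if p == 0.0:
                continue
            up = (L - dd) / L if dd < L else 0.0
            down = (dd / L) / 3.0
            stay = 1.0 - up - down
            if dd + 1 <= dmax:
                new[dd + 1] += p * up
            if dd - 1 >= 0:
                new[dd - 1] += p * down
            new[dd] += p * stay
        dist = new
        if m >= j:
            probs[m - j] = dist[j] if j <= dmax else 0.0
    return probs


def parsimony_probability(L: int, j: int, max_extra: int = 60) -> float:
    """Probability that j observed differences over L sites reflect exactly j mutations."""
    if j == 0:
        return 1.0
    probs = _prob_diff_given_mutations(L, j, max_extra)
    total = probs.sum()
    if total <= 0:
        return 0.0
    return float(probs[0] / total)


def parsimony_connection_limit(L: int, alpha: float = 0.95) -> ParsimonyLimit:
    """Largest step count whose parsimony probability is >= alpha (at least 1)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    j = 1
    while j < L and parsimony_probability(L, j + 1) >= alpha:
        j += 1
    return ParsimonyLimit(L=L, alpha=alpha, max_steps=j)


@dataclass
class HaplotypeNetwork:
    """Unit-step haplotype graph.

    Node attributes: ``kind`` ("sampled" | "intermediate"), ``count`` (sampled
    frequency; 0 for intermediates), ``sequence`` (sampled only).  Edge
    attribute ``steps`` is 1 except for the rare 0-step link between
    haplotypes distinguished only at ambiguous/gap columns; ``forced`` marks
    edges added beyond the parsimony limit.
    """

    graph: nx.Graph
    haplotype_names: list[str]
    limit: ParsimonyLimit | None = None

    def components(self) -> list[set]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def sampled_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "sampled"]


def build_network(
    haps: HaplotypeSet,
    limit: ParsimonyLimit | None = None,
    force_connect: bool = True,
    alpha: float = 0.95,
) -> HaplotypeNetwork:
    """Kruskal-style statistical parsimony network over a haplotype set.

    Pairs are visited in nondecreasing step order (ties by haplotype index)
    and joined only when still in different components, inserting steps-1
    intermediate nodes per connection.  Pairs beyond the limit are skipped
    unless ``force_connect``, in which case residual components are joined
    through their minimum inter-component pair with the edge run flagged.
    """
    if not haps.sequences:
        raise NetworkError("empty haplotype set")
    if limit is None:
        L = len(haps.sequences[0])
        limit = parsimony_connection_limit(max(L, 1), alpha)
    steps = pairwise_steps(haps)
    g = nx.Graph()
    for name, seq, members in zip(haps.names, haps.sequences, haps.membership):
        g.add_node(name, kind="sampled", count=len(members), sequence=seq)
    n = len(haps.names)
    pairs = sorted(
        ((int(steps[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda t: t,
    )
    counter = 0

    def connect(i: int, j: int, k: int, forced: bool) -> None:
        nonlocal counter
        a, b = haps.names[i], haps.names[j]
        if k <= 1:
            g.add_edge(a, b, steps=k, forced=forced)
            return
        prev = a
        for _ in range(k - 1):
            mid = f"x{counter}"
            counter += 1
            g.add_node(mid, kind="intermediate", count=0)
            g.add_edge(prev, mid, steps=1, forced=forced)
            prev = mid
        g.add_edge(prev, b, steps=1, forced=forced)

    for k, i, j in pairs:
        if k > limit.max_steps:
            break
        a, b = haps.names[i], haps.names[j]
        if not nx.has_path(g, a, b):
            connect(i, j, k, forced=False)
    if force_connect:
        for k, i, j in pairs:
            if k <= limit.max_steps:
                continue
            a, b = haps.names[i], haps.names[j]
            if not nx.has_path(g, a, b):
                connect(i, j, k, forced=True)
    return HaplotypeNetwork(g, list(haps.names), limit)


def _step_weight(u, v, data) -> float:
    return float(data.get("steps", 1))


@dataclass
class PathMetrics:
    names: list[str]
    step_matrix: np.ndarray                  # shortest-path steps between sampled haplotypes
    subgroup_diameter: dict[str, int]
    subgroup_variable_positions: dict[str, int]


def path_metrics(
    net: HaplotypeNetwork,
    subgroups: dict[str, str] | None = None,
    haps: HaplotypeSet | None = None,
) -> PathMetrics:
    """Shortest-path step counts, per-subgroup diameters and variable-site counts.

    ``subgroups`` maps haplotype names to labels; a subgroup's diameter is its
    longest shortest path, and its variable-position count is the number of
    alignment columns with more than one unambiguous state among its member
    haplotype sequences.  Raises on disconnected name pairs (run with
    force_connect or compute per component).
    """
    names = net.haplotype_names
    for nm in subgroups or {}:
        if nm not in net.graph:
            raise NetworkError(f"node {nm!r} not in network")
    n = len(names)
    M = np.zeros((n, n), dtype=int)
    for i, a in enumerate(names):
        lengths = nx.single_source_dijkstra_path_length(net.graph, a, weight=_step_weight)
        for j, b in enumerate(names):
            if b not in lengths:
                raise NetworkError(f"no path between {a!r} and {b!r} (disconnected network)")
            M[i, j] = int(round(lengths[b]))
    diam: dict[str, int] = {}
    varpos: dict[str, int] = {}
    if subgroups:
        seq_of = {}
        for nm in names:
            seq = net.graph.nodes[nm].get("sequence")
            if seq is None and haps is not None:
                seq = haps.sequence_of(nm)
            seq_of[nm] = seq
        idx = {nm: i for i, nm in enumerate(names)}
        for label in sorted(set(subgroups.values())):
            members = [nm for nm, lab in subgroups.items() if lab == label]
            ids = [idx[nm] for nm in members]
            diam[label] = int(M[np.ix_(ids, ids)].max()) if ids else 0
            seqs = [seq_of[nm] for nm in members if seq_of[nm] is not None]
            count = 0
            if seqs:
                for col in zip(*seqs):
                    states = {c for c in col if c in UNAMBIGUOUS}
                    if len(states) > 1:
                        count += 1
            varpos[label] = count
    return PathMetrics(list(names), M, diam, varpos)


def parsimony_component(net: HaplotypeNetwork, node: str | None = None) -> set[str]:
    """Sampled haplotypes reachable from ``node`` without forced edges.

    With ``node`` omitted, the highest-frequency haplotype anchors the search.
    On barcode data this component is the focal haplogroup: lineages that only
    join through beyond-limit (forced) connections — early-diverging outliers,
    congeners — are excluded, which is how the design stage finds the set of
    haplotypes an inclusive assay must cover.
    """
    g = nx.Graph(
        (u, v) for u, v, d in net.graph.edges(data=True) if not d.get("forced", False)
    )
    g.add_nodes_from(net.graph.nodes)
    if node is None:
        node = max(
            net.haplotype_names, key=lambda n: (net.graph.nodes[n]["count"], n)
        )
    comp = nx.node_connected_component(g, node)
    return {n for n in comp if net.graph.nodes[n]["kind"] == "sampled"}


def network_edge_table(net: HaplotypeNetwork) -> "list[dict]":
    """TSV-ready edge list with unit-edge runs through intermediates merged."""
    g = net.graph
    rows = []
    seen = set()
    for a in net.haplotype_names:
        for b in g.neighbors(a):
            path = [a, b]
            while g.nodes[path[-1]]["kind"] == "intermediate":
                nxts = [x for x in g.neighbors(path[-1]) if x != path[-2]]
                if not nxts:
                    break
                path.append(nxts[0])
            end = path[-1]
            if g.nodes[end]["kind"] != "sampled":
                continue
            key = frozenset((a, end))
            if key in seen:
                continue
            seen.add(key)
            steps = sum(g.edges[u, v]["steps"] for u, v in zip(path, path[1:]))
            forced = any(g.edges[u, v].get("forced", False) for u, v in zip(path, path[1:]))
            rows.append({"from": a, "to": end, "steps": steps, "forced": forced})
    return rows
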