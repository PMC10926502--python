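"""Shared fixtures and small independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from barcodedx.alignment import Alignment, SampleRecord, SampleTable


def make_table(groups: dict[str, str], **extra) -> SampleTable:
    """Quick sample table from an id -> group mapping."""
    recs = []
    for sid, group in groups.items():
        recs.append(
            SampleRecord(
                sample_id=sid,
                species=extra.get("species", {}).get(sid, "sp"),
                group=group,
                subspecies=extra.get("subspecies", {}).get(sid, ""),
                locality="", source="",
            )
        )
    return SampleTable.from_records(recs)


def random_alignment(rng: np.random.Generator, n: int, L: int, gap_p: float = 0.0) -> Alignment:
    bases = np.array(list("ACGT"))
    rows = []
    for i in range(n):
        row = bases[rng.integers(0, 4, size=L)]
        if gap_p:
            mask = rng.random(L) < gap_p
            row = np.where(mask, "-", row)
        rows.append("".join(row))
    return Alignment([f"s{i}" for i in range(n)], rows)


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf path-length matrix (the additive-metric oracle for NJ)."""
    import networkx as nx

    g = nx.Graph()
    leaves = [f"L{i}" for i in range(n_leaves)]
    nodes = list(leaves)
    nxt = 0
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = f"I{nxt}"
        nxt += 1
        g.add_edge(a, parent, length=float(rng.uniform(0.05, 1.0)))
        g.add_edge(b, parent, length=float(rng.uniform(0.05, 1.0)))
        nodes = [x for x in nodes if x not in (a, b)] + [parent]
    g.add_edge(nodes[0], nodes[1], length=float(rng.uniform(0.05, 1.0)))
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(leaves):
        for j, b in enumerate(leaves):
            D[i, j] = lengths[a][b]
    return leaves, D


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
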