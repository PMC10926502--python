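"""TN93 distances, neighbor joining, jackknife support, clade composition."""

import math

import networkx as nx
import numpy as np
import pytest

from barcodedx.alignment import Alignment
from barcodedx.errors import DistanceError, MetadataError
from barcodedx.phylo import (
    DistanceMatrix, PhyloTree, clade_composition, jackknife_support,
    jc69_distance, neighbor_joining, tn93_distance,
)

from conftest import make_table, random_additive_tree


def matrix(labels, entries):
    n = len(labels)
    D = np.zeros((n, n))
    for (i, j), v in entries.items():
        D[i, j] = D[j, i] = v
    return DistanceMatrix(labels, D, np.zeros((n, n), dtype=bool))


class TestTN93:
    def test_identical_sequences_zero(self):
        aln = Alignment(["a", "b"], ["ACGTACGT", "ACGTACGT"])
        assert tn93_distance(aln).matrix[0, 1] == 0.0

    def test_total_divergence_saturates(self):
        aln = Alignment(["a", "b"], ["A" * 50, "G" * 50])
        dm = tn93_distance(aln)
        assert dm.saturated[0, 1]
        assert math.isnan(dm.matrix[0, 1])

    def test_hand_evaluated_closed_form(self):
        # 100-nt pair with 4 A<->G, 3 C<->T and 3 transversion differences
        s1 = list("A" * 30 + "C" * 25 + "G" * 25 + "T" * 20)
        s2 = list(s1)
        for k in range(4):          # A -> G transitions
            s2[k] = "G"
        for k in range(30, 33):     # C -> T transitions
            s2[k] = "T"
        for k in range(55, 58):     # G -> C transversions
            s2[k] = "C"
        aln = Alignment(["a", "b"], ["".join(s1), "".join(s2)])
        got = tn93_distance(aln).matrix[0, 1]
        # independent evaluation of the closed form from the counted quantities
        P1, P2, Q = 0.04, 0.03, 0.03
        counts = {"A": 30 + 26, "C": 25 + 25, "G": 25 + 26, "T": 20 + 23}
        tot = sum(counts.values())
        pA, pC, pG, pT = (counts[b] / tot for b in "ACGT")
        pR, pY = pA + pG, pC + pT
        expect = (
            -(2 * pA * pG / pR) * math.log(1 - pR * P1 / (2 * pA * pG) - Q / (2 * pR))
            - (2 * pC * pT / pY) * math.log(1 - pY * P2 / (2 * pC * pT) - Q / (2 * pY))
            - 2 * (pR * pY - pA * pG * pY / pR - pC * pT * pR / pY)
            * math.log(1 - Q / (2 * pR * pY))
        )
        assert got == pytest.approx(expect, abs=1e-12)

    def test_equals_jc69_under_symmetric_construction(self):
        # equal base composition, one difference of each unordered type in each
        # direction: TN93 collapses to the Jukes-Cantor estimate exactly
        s1 = list("A" * 30 + "C" * 30 + "G" * 30 + "T" * 30)
        s2 = list(s1)
        swaps = [  # (position in s1's block, new base), balanced per type
            (0, "G"), (60, "A"),    # A<->G
            (30, "T"), (90, "C"),   # C<->T
            (1, "C"), (31, "A"),    # A<->C
            (2, "T"), (91, "A"),    # A<->T
            (32, "G"), (61, "C"),   # C<->G
            (62, "T"), (92, "G"),   # G<->T
        ]
        for pos, base in swaps:
            s2[pos] = base
        aln = Alignment(["a", "b"], ["".join(s1), "".join(s2)])
        d = tn93_distance(aln).matrix[0, 1]
        assert d == pytest.approx(jc69_distance(12 / 120), abs=1e-9)

    def test_no_comparable_sites_errors(self):
        aln = Alignment(["a", "b"], ["AC--", "--GT"])
        with pytest.raises(DistanceError, match="a.*b"):
            tn93_distance(aln)

    def test_gap_columns_excluded_pairwise(self):
        aln = Alignment(["a", "b"], ["AC-T", "ACGT"])
        assert tn93_distance(aln).matrix[0, 1] == 0.0


class TestNeighborJoining:
    def test_three_taxon_analytic_lengths(self):
        D = matrix(["A", "B", "C"], {(0, 1): 2.0, (0, 2): 3.0, (1, 2): 5.0})
        tree = neighbor_joining(D)
        g = tree.graph
        internal = [n for n in g.nodes if not isinstance(n, str)][0]
        assert g.edges["A", internal]["length"] == pytest.approx(0.0)
        assert g.edges["B", internal]["length"] == pytest.approx(2.0)
        assert g.edges["C", internal]["length"] == pytest.approx(3.0)

    def test_recovers_additive_tree(self, rng):
        labels, D = random_additive_tree(rng, 6)
        dm = DistanceMatrix(labels, D, np.zeros_like(D, dtype=bool))
        tree = neighbor_joining(dm)
        assert np.allclose(tree.path_length_matrix(), D, atol=1e-9)

    def test_deterministic_under_ties(self):
        D = matrix(["A", "B", "C", "D"],
                   {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 2.0,
                    (1, 2): 1.0, (1, 3): 2.0, (2, 3): 2.0})
        n1 = neighbor_joining(D).newick()
        n2 = neighbor_joining(D).newick()
        assert n1 == n2

    def test_label_order_invariant_metric(self, rng):
        labels, D = random_additive_tree(rng, 7)
        dm = DistanceMatrix(labels, D, np.zeros_like(D, dtype=bool))
        M1 = neighbor_joining(dm).path_length_matrix()
        perm = rng.permutation(len(labels))
        labels2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        dm2 = DistanceMatrix(labels2, D2, np.zeros_like(D2, dtype=bool))
        tree2 = neighbor_joining(dm2)
        order = [labels2.index(l) for l in labels]
        M2 = tree2.path_length_matrix()[np.ix_(order, order)]
        assert np.allclose(M1, M2, atol=1e-9)

    def test_saturated_entries_rejected(self):
        D = matrix(["A", "B", "C"], {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0})
        D.saturated[0, 1] = D.saturated[1, 0] = True
        with pytest.raises(DistanceError, match="saturated"):
            neighbor_joining(D)


def two_group_alignment(rng, n_per_group=5, L=150, n_fixed=30):
    """Two clusters separated by n_fixed fixed differences, plus one private
    mutation per sample so every sequence is distinct."""
    bases = "ACGT"
    base = "".join(bases[i] for i in rng.integers(0, 4, size=L))
    other = list(base)
    fixed_cols = list(range(n_fixed))
    for j in fixed_cols:
        other[j] = bases[(bases.index(other[j]) + 1) % 4]
    other = "".join(other)
    ids, rows = [], []
    free = list(range(n_fixed, L))
    for g, stem in (("p", base), ("q", other)):
        for k in range(n_per_group):
            col = free.pop()
            row = list(stem)
            row[col] = bases[(bases.index(row[col]) + 1) % 4]
            ids.append(f"{g}{k}")
            rows.append("".join(row))
    return Alignment(ids, rows)


class TestJackknife:
    def test_fixed_separation_gets_full_support(self, rng):
        aln = two_group_alignment(rng)
        tree = jackknife_support(aln, replicates=200, seed=5)
        bips = tree.bipartitions()
        split = frozenset(s for s in aln.sample_ids if s.startswith("q"))
        key = split if split in bips else frozenset(set(aln.sample_ids) - split)
        assert key in bips
        assert tree.graph.edges[bips[key]]["support"] == 100.0

    def test_zero_replicates_rejected(self, rng):
        aln = two_group_alignment(rng)
        with pytest.raises(ValueError):
            jackknife_support(aln, replicates=0)

    def test_seed_reproducible(self, rng):
        aln = two_group_alignment(rng, n_per_group=3, L=100, n_fixed=12)
        t1 = jackknife_support(aln, replicates=50, seed=7)
        t2 = jackknife_support(aln, replicates=50, seed=7)
        s1 = sorted(d["support"] for _, _, d in t1.graph.edges(data=True) if "support" in d)
        s2 = sorted(d["support"] for _, _, d in t2.graph.edges(data=True) if "support" in d)
        assert s1 == s2

    def test_column_order_invariant_on_supported_branch(self, rng):
        # deterministic column-order invariance: the branch carried by fixed
        # differences scores 100 regardless of how columns are arranged
        aln = two_group_alignment(rng)
        perm = rng.permutation(aln.L)
        shuffled = Alignment(
            list(aln.sample_ids), ["".join(r[j] for j in perm) for r in aln.rows]
        )
        split = frozenset(s for s in aln.sample_ids if s.startswith("q"))
        for a in (aln, shuffled):
            tree = jackknife_support(a, replicates=50, seed=3)
            bips = tree.bipartitions()
            key = split if split in bips else frozenset(set(a.sample_ids) - split)
            assert tree.graph.edges[bips[key]]["support"] == 100.0


class TestCladeComposition:
    def manual_tree(self):
        g = nx.Graph()
        g.add_edge("a1", 0, length=1.0)
        g.add_edge("a2", 0, length=1.0)
        g.add_edge(0, 1, length=1.0)
        g.add_edge("b1", 1, length=1.0)
        g.add_edge("o", 1, length=1.0)
        return PhyloTree(g, ["a1", "a2", "b1", "o"], outgroup="o")

    def test_simple_monophyly_and_percentages(self):
        tree = self.manual_tree()
        table = make_table({"a1": "target", "a2": "target", "b1": "nontarget", "o": "outgroup"},
                           species={"a1": "A", "a2": "A", "b1": "B", "o": "O"})
        rep = clade_composition(tree, table, "species")
        assert rep["monophyly"] == {"A": True, "B": True, "O": True}
        comps = [c["composition"] for c in rep["clades"]]
        assert {"A": 100.0} in comps

    def test_mixed_clade_percentages(self):
        g = nx.Graph()
        leaves = [f"x{i}" for i in range(8)] + ["o"]
        hub = 0
        for i, lf in enumerate(leaves[:8]):
            g.add_edge(lf, hub, length=1.0)
        g.add_edge(hub, 1, length=1.0)
        g.add_edge("o", 1, length=1.0)
        tree = PhyloTree(g, leaves, outgroup="o")
        species = {f"x{i}": ("X" if i < 5 else "Y") for i in range(8)}
        species["o"] = "O"
        table = make_table({lf: "target" for lf in leaves}, species=species)
        rep = clade_composition(tree, table, "species")
        big = max(rep["clades"], key=lambda c: c["size"])
        assert big["composition"]["X"] == pytest.approx(62.5)
        assert big["composition"]["Y"] == pytest.approx(37.5)

    def test_monophyly_matches_bruteforce(self, rng):
        labels, D = random_additive_tree(rng, 12)
        dm = DistanceMatrix(labels, D, np.zeros_like(D, dtype=bool))
        tree = neighbor_joining(dm)
        species = {lab: rng.choice(["X", "Y", "Z"]) for lab in labels}
        table = make_table({lab: "target" for lab in labels}, species=species)
        rep = clade_composition(tree, table, "species")
        sides = set()
        for side in tree.bipartitions():
            sides.add(side)
            sides.add(frozenset(set(labels) - side))
        for sp in set(species.values()):
            members = frozenset(l for l in labels if species[l] == sp)
            expect = len(members) == 1 or members in sides or members == frozenset(labels)
            assert rep["monophyly"][sp] == expect

    def test_unlabeled_leaf_errors(self):
        tree = self.manual_tree()
        table = make_table({"a1": "target", "a2": "target", "b1": "nontarget"})
        with pytest.raises(MetadataError, match="o"):
            clade_composition(tree, table, "species")
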