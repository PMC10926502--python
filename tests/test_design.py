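"""SNV scanning, candidate enumeration, assay ranking, control design, specificity."""

import warnings

import numpy as np
import pytest

from barcodedx.alignment import Alignment, consensus_sequence, detect_diagnostic_sites
from barcodedx.design import (
    OligoCandidate, OligoConstraints, SiteFlags, design_assay,
    design_control_assay, discriminative_support, enumerate_candidates,
    in_silico_specificity, passes_hard_constraints, rank_assay_sets,
    site_flags, snv_density_scan,
)
from barcodedx.errors import DesignError
from barcodedx.simulate import generate_barcode_dataset, generate_control_dataset
from barcodedx.thermo import reverse_complement, structure_screen, tm_nearest_neighbor

from conftest import make_table


def labeled_alignment(rows_by_group):
    """rows_by_group: list of (id, group, sequence)."""
    ids = [r[0] for r in rows_by_group]
    groups = {r[0]: r[1] for r in rows_by_group}
    rows = [r[2] for r in rows_by_group]
    return Alignment(ids, rows), make_table(groups)


def planted_scan_alignment(L=200, n_fixed=5, window_start=100):
    """Target/nontarget pair groups differing only inside one dense window."""
    rng = np.random.default_rng(77)
    bases = "ACGT"
    base = "".join(bases[i] for i in rng.integers(0, 4, size=L))
    other = list(base)
    for k in range(n_fixed):
        j = window_start + 5 * k
        other[j] = bases[(bases.index(other[j]) + 1) % 4]
    return labeled_alignment([
        ("t1", "target", base), ("t2", "target", base),
        ("n1", "nontarget", "".join(other)), ("n2", "nontarget", "".join(other)),
    ])


class TestSnvDensityScan:
    def test_dense_window_ranks_first(self):
        aln, table = planted_scan_alignment()
        wins = snv_density_scan(aln, table)
        assert wins[0].score == 5.0
        lo, hi = wins[0].segment
        assert lo <= 100 and hi >= 121  # covers all five planted differences

    def test_invariant_alignment_is_empty_with_warning(self):
        aln, table = labeled_alignment([
            ("t1", "target", "ACGT" * 50), ("n1", "nontarget", "ACGT" * 50),
        ])
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            assert snv_density_scan(aln, table) == []
        assert any("no segment" in str(x.message) for x in w)

    def test_ranking_matches_bruteforce(self, rng):
        # random labeled alignment: segment ranking equals an exhaustive scan
        bases = "ACGT"
        L = 200
        base = "".join(bases[i] for i in rng.integers(0, 4, size=L))
        other = list(base)
        for j in rng.choice(L, size=8, replace=False):   # fixed differences
            other[j] = bases[(bases.index(other[j]) + 1) % 4]
        rows = []
        for i in range(12):
            row = list(base if i < 6 else other)
            for j in rng.choice(L, size=2, replace=False):  # private noise
                row[j] = bases[(bases.index(row[j]) + rng.integers(1, 4)) % 4]
            rows.append("".join(row))
        ids = [f"s{i}" for i in range(12)]
        groups = {sid: ("target" if i < 6 else "nontarget") for i, sid in enumerate(ids)}
        aln = Alignment(ids, rows)
        table = make_table(groups)
        seg = 120
        wins = snv_density_scan(aln, table, segment_len=seg)
        flags = site_flags(aln, table)
        col = flags.fixed_difference.astype(float) - flags.intra_target_variable.astype(float)
        expect = sorted(
            (
                (float(col[s : s + seg].sum()), s)
                for s in range(L - seg + 1)
                if col[s : s + seg].sum() > 0
            ),
            key=lambda t: (-t[0], t[1]),
        )
        assert [(w.score, w.segment[0]) for w in wins] == expect

    def test_score_equals_fixed_difference_count_when_target_invariant(self):
        aln, table = planted_scan_alignment()
        wins = snv_density_scan(aln, table, lam=1.0)
        lo, hi = wins[0].segment
        rep = detect_diagnostic_sites(aln, table)
        fixed = rep[rep["classification"] == "fixed_difference"]
        in_seg = fixed[(fixed["position"] > lo) & (fixed["position"] <= hi)]
        assert wins[0].score == float(len(in_seg))


class TestEnumerateCandidates:
    def test_window_shorter_than_min_length_empty(self):
        aln, table = planted_scan_alignment()
        out = enumerate_candidates((0, 10), aln, table, OligoConstraints(), "forward")
        assert out == []

    def test_candidates_pass_all_hard_constraints(self):
        aln, table, _ = generate_barcode_dataset(seed=3)
        c = OligoConstraints()
        flags = site_flags(aln, table)
        cons = consensus_sequence(aln, [s for s in aln.sample_ids if table.group_of(s) == "target"])
        for role, win in (("forward", (140, 170)), ("probe", (175, 205)), ("reverse", (215, 245))):
            for cand in enumerate_candidates(win, aln, table, c, role, flags, cons):
                ok, _, why = passes_hard_constraints(cand.sequence, role, c)
                assert ok, why
                assert c.len_for(role).min <= len(cand.sequence) <= c.len_for(role).max

    def test_matches_bruteforce_enumeration(self):
        # exhaustive oracle over one <= 40 nt window of the target consensus
        aln, table, _ = generate_barcode_dataset(seed=3)
        c = OligoConstraints(candidates_per_window=10_000)
        flags = site_flags(aln, table)
        cons = consensus_sequence(aln, [s for s in aln.sample_ids if table.group_of(s) == "target"])
        lo, hi = 150, 190
        got = {
            (cand.interval, cand.sequence)
            for cand in enumerate_candidates((lo, hi), aln, table, c, "forward", flags, cons)
        }
        expect = set()
        for start in range(lo, hi):
            for end in range(start + 14, min(start + 35, hi) + 1):
                top = cons[start:end]
                if any(ch not in "ACGT" for ch in top):
                    continue
                intra = [j for j in range(start, end) if flags.intra_target_variable[j]]
                if any(j >= end - 3 for j in intra):
                    continue
                tm = tm_nearest_neighbor(top)
                gc = 100.0 * (top.count("G") + top.count("C")) / len(top)
                scr = structure_screen(top)
                if not (50.0 <= tm <= 60.0 and 20.0 <= gc <= 80.0):
                    continue
                if scr.poly_x > 5 or scr.three_prime_stability > 9.0 or scr.self_dimer_tm > 47.0:
                    continue
                expect.add(((start, end), top))
        assert got == expect


class TestDiscriminativeSupport:
    def flags_for(self, L, fixed_at):
        fixed = np.zeros(L, dtype=bool)
        fixed[list(fixed_at)] = True
        return SiteFlags(fixed, np.zeros(L, dtype=bool), np.zeros(L, dtype=bool))

    def cand(self, start, end):
        return OligoCandidate(
            sequence="A" * (end - start), role="forward", interval=(start, end),
            tm_nn=55.0, tm_salt=None, gc_percent=50.0, structure=None,
        )

    def test_midfootprint_variants_weigh_one(self):
        flags = self.flags_for(60, [25, 27, 29])
        count, pos, score = discriminative_support(self.cand(15, 40), flags, OligoConstraints())
        assert (count, score) == (3, 3.0)
        assert pos == [26, 28, 30]

    def test_terminal_variants_weigh_double(self):
        flags = self.flags_for(60, [15, 16, 38])
        count, _, score = discriminative_support(self.cand(15, 40), flags, OligoConstraints())
        assert (count, score) == (3, 6.0)

    def test_matches_bruteforce_positions(self, rng):
        L = 80
        fixed_at = rng.choice(L, size=12, replace=False)
        flags = self.flags_for(L, fixed_at)
        start, end = 20, 50
        count, pos, score = discriminative_support(self.cand(start, end), flags, OligoConstraints())
        expect_pos = sorted(int(j) + 1 for j in fixed_at if start <= j < end)
        assert pos == expect_pos and count == len(expect_pos)
        expect_score = sum(
            2.0 if (p - 1 - start) < 5 or (end - p) < 5 else 1.0 for p in expect_pos
        )
        assert score == expect_score


def make_candidate(role, start, end, tm, disc=3, disc_positions=None, seq=None):
    n = end - start
    seq = seq or ("ACGT" * 20)[:n]
    if role == "reverse":
        seq = reverse_complement(seq)
    pos = disc_positions or list(range(start + 6, start + 6 + disc))
    return OligoCandidate(
        sequence=seq, role=role, interval=(start, end), tm_nn=tm, tm_salt=None,
        gc_percent=50.0, structure=structure_screen(seq),
        disc_count=disc, disc_positions=[p + 1 for p in pos],
        end_weighted_score=float(disc),
    )


class TestRankAssaySets:
    def triple(self, disc=3):
        f = make_candidate("forward", 0, 20, 55.0, disc=disc,
                           disc_positions=[17, 18, 19][:max(1, disc)])
        p = make_candidate("probe", 25, 45, 61.0, disc=disc)
        r = make_candidate("reverse", 50, 70, 55.5, disc=disc,
                           disc_positions=[50, 51, 52][:max(1, disc)])
        return f, r, p

    def test_single_feasible_triple_is_rank_one(self):
        f, r, p = self.triple()
        out = rank_assay_sets([f], [r], [p], OligoConstraints())
        assert len(out) == 1 and out[0].rank == 1

    def test_higher_discriminative_count_wins(self):
        f1, r1, p1 = self.triple(disc=2)
        f2, _, _ = self.triple(disc=4)
        out = rank_assay_sets([f1, f2], [r1], [p1], OligoConstraints())
        assert out[0].forward.disc_count == 4

    def test_probe_must_be_hotter_than_primers(self):
        f, r, p = self.triple()
        cold_probe = make_candidate("probe", 25, 45, 54.0)
        out = rank_assay_sets([f], [r], [cold_probe], OligoConstraints())
        assert out == []

    def test_order_invariant_to_input_permutation(self, rng):
        fs = [make_candidate("forward", 0, 20, 54.0 + k, disc=k + 1,
                             disc_positions=[17, 18, 19][: k + 1]) for k in range(3)]
        rs = [make_candidate("reverse", 50, 70, 54.0 + k, disc=k + 1,
                             disc_positions=[50, 51, 52][: k + 1]) for k in range(3)]
        ps = [make_candidate("probe", 25, 45, 61.0 + k, disc=k + 1) for k in range(2)]
        a = rank_assay_sets(fs, rs, ps, OligoConstraints())
        b = rank_assay_sets(fs[::-1], rs[::-1], ps[::-1], OligoConstraints())
        key = lambda s: (s.forward.interval, s.reverse.interval, s.probe.interval,
                         s.forward.tm_nn, s.reverse.tm_nn, s.probe.tm_nn)
        assert [key(s) for s in a] == [key(s) for s in b]

    def test_full_ordering_matches_bruteforce_sort(self):
        fs = [make_candidate("forward", 0, 20, 54.0 + k, disc=k + 1,
                             disc_positions=[17, 18, 19][: k + 1]) for k in range(3)]
        rs = [make_candidate("reverse", 50, 70, 54.0 + k, disc=k + 1,
                             disc_positions=[50, 51, 52][: k + 1]) for k in range(3)]
        ps = [make_candidate("probe", 25, 45, 61.0 + k, disc=k + 1) for k in range(2)]
        out = rank_assay_sets(fs, rs, ps, OligoConstraints())
        keys = [
            (-s.total_disc, -s.end_weighted, -s.tm_differential, s.structure_penalty)
            for s in out
        ]
        assert keys == sorted(keys)


class TestControlAssay:
    def test_designed_inside_conserved_block_with_tm_cap(self):
        aln, table, _ = generate_barcode_dataset(seed=1)
        ctrl_aln = generate_control_dataset(table, seed=101)
        diag = design_pipeline_first_assay()
        ctrl = design_control_assay(ctrl_aln, table, diag)
        assert ctrl.forward.tm_nn <= diag.forward.tm_nn
        assert ctrl.reverse.tm_nn <= diag.reverse.tm_nn
        assert ctrl.probe.tm_nn <= diag.probe.tm_nn
        flags = site_flags(ctrl_aln, table)
        for o in ctrl.oligos():
            assert flags.conserved_all[o.interval[0] : o.interval[1]].all()

    def test_no_conserved_block_errors(self):
        rng = np.random.default_rng(5)
        bases = "ACGT"
        L = 200
        base = "".join(bases[i] for i in rng.integers(0, 4, size=L))
        noisy = list(base)
        for j in range(0, L, 10):  # variation every 10 nt: no 54-nt clean run
            noisy[j] = bases[(bases.index(noisy[j]) + 1) % 4]
        aln, table = labeled_alignment([
            ("t1", "target", base), ("n1", "nontarget", "".join(noisy)),
        ])
        diag = design_pipeline_first_assay()
        with pytest.raises(DesignError, match="conserv"):
            design_control_assay(aln, table, diag)


def design_pipeline_first_assay():
    aln, table, truth = generate_barcode_dataset(seed=1)
    design_ids = [
        s for s in aln.sample_ids
        if table.group_of(s) != "target" or truth["lineage"][s] == "main"
    ]
    return design_assay(aln.subset(design_ids), table)[0]


class TestInSilicoSpecificity:
    def test_target_consensus_predicted_positive(self):
        aln, table, truth = generate_barcode_dataset(seed=1)
        assay = design_pipeline_first_assay()
        rep = in_silico_specificity(assay, aln, table)
        rep = rep.set_index("sample_id")
        for sid in truth["main_sample_ids"]:
            assert rep.loc[sid, "predicted_amplification"]

    def test_nontargets_predicted_negative(self):
        aln, table, truth = generate_barcode_dataset(seed=1)
        assay = design_pipeline_first_assay()
        rep = in_silico_specificity(assay, aln, table).set_index("sample_id")
        for sid, lin in truth["lineage"].items():
            if lin.startswith("nt_") or lin == "outgroup":
                assert not rep.loc[sid, "predicted_amplification"]

    def test_three_prime_mismatch_kills_amplification(self):
        aln, table, truth = generate_barcode_dataset(seed=1)
        assay = design_pipeline_first_assay()
        sid = truth["main_sample_ids"][0]
        row = list(aln.row(sid))
        j = assay.forward.interval[1] - 1   # forward primer 3' terminus
        row[j] = "ACGT"[("ACGT".index(row[j]) + 1) % 4]
        mut = Alignment([sid], ["".join(row)])
        rep = in_silico_specificity(assay, mut, table)
        assert not rep.iloc[0]["predicted_amplification"]

    def test_mismatch_counts_match_bruteforce(self):
        aln, table, _ = generate_barcode_dataset(seed=1)
        assay = design_pipeline_first_assay()
        rep = in_silico_specificity(assay, aln, table).set_index("sample_id")
        for sid in aln.sample_ids[::7]:
            row = aln.row(sid)
            for oligo, col in ((assay.forward, "forward_mismatches"),
                               (assay.probe, "probe_mismatches")):
                start, end = oligo.interval
                top = oligo.sequence
                expect = sum(1 for k, j in enumerate(range(start, end)) if row[j] != top[k])
                assert rep.loc[sid, col] == expect

    def test_footprint_outside_panel_errors(self):
        aln, table, _ = generate_barcode_dataset(seed=1)
        assay = design_pipeline_first_assay()
        short = Alignment(list(aln.sample_ids), [r[:100] for r in aln.rows])
        with pytest.raises(DesignError, match="footprint"):
            in_silico_specificity(assay, short, table)
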