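"""Consensus-guided diagnostic primer/probe design.

The procedure mirrors TaqMan assay development against an aligned barcode
matrix: scan for segments dense in fixed target/nontarget differences and
sparse in intra-target variation, enumerate Primer3-style candidates on the
target-group consensus inside ~30-nt windows, screen them against the
thermodynamic and structural constraint set, score their discriminative
support (fixed differences under the footprint, end-weighted), and rank
forward/reverse/probe triples.  A control assay is designed the same way but
on conservation instead of difference, with Tm at or below the diagnostic
oligos.  In-silico specificity replaces a database search with mismatch
counting against a user-supplied panel sharing the alignment coordinates.

All intervals are 0-based half-open on the alignment top strand; reverse-role
oligo sequences are stored as the reverse complement of that strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import (
    Alignment, SampleTable, UNAMBIGUOUS,
    consensus_sequence,
)
from .errors import DesignError
from .thermo import (
    StructureScores, gc_fraction, reverse_complement, structure_screen,
    tm_nearest_neighbor, tm_salt_adjusted,
)


@dataclass
class Triple:
    min: float
    opt: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.opt <= self.max):
            raise ValueError(f"need min <= opt <= max, got {self}")

    def contains(self, x: float) -> bool:
        return self.min <= x <= self.max


@dataclass
class OligoConstraints:
    """Primer3-style constraint set for the diagnostic assay."""

    monovalent_molar: float = 0.05
    divalent_molar: float = 0.0015
    strand_molar: float = 5e-8
    dntp_molar: float = 6e-4
    primer_tm: Triple = field(default_factory=lambda: Triple(50.0, 55.5, 60.0))
    probe_tm: Triple = field(default_factory=lambda: Triple(57.0, 60.0, 63.0))
    gc_percent: Triple = field(default_factory=lambda: Triple(20.0, 50.0, 80.0))
    primer_len: Triple = field(default_factory=lambda: Triple(14, 22, 35))
    probe_len: Triple = field(default_factory=lambda: Triple(18, 20, 36))
    max_dimer_tm: float = 47.0
    max_poly_x: int = 5
    max_three_prime_stability: float = 9.0
    candidates_per_window: int = 5
    #: weight on positions within this many bases of either oligo end
    end_weight_span: int = 5
    end_weight: float = 2.0

    def tm_for(self, role: str) -> Triple:
        return self.probe_tm if role == "probe" else self.primer_tm

    def len_for(self, role: str) -> Triple:
        return self.probe_len if role == "probe" else self.primer_len

    def tm_args(self) -> dict:
        return dict(
            na_molar=self.monovalent_molar,
            mg_molar=self.divalent_molar,
            dntp_molar=self.dntp_molar,
            strand_molar=self.strand_molar,
        )


# --- column classification used by scanning ---------------------------------

@dataclass
class SiteFlags:
    fixed_difference: np.ndarray     # bool per column: target vs nontarget fixed
    intra_target_variable: np.ndarray
    conserved_all: np.ndarray        # single unambiguous state across every sample


def site_flags(aln: Alignment, table: SampleTable) -> SiteFlags:
    table.validate_against(aln)
    tgt_ids = [s for s in aln.sample_ids if table.group_of(s) == "target"]
    non_ids = [s for s in aln.sample_ids if table.group_of(s) == "nontarget"]
    if not tgt_ids or not non_ids:
        raise DesignError("design needs at least one target and one nontarget sample")
    L = aln.L
    fixed = np.zeros(L, dtype=bool)
    intra = np.zeros(L, dtype=bool)
    cons = np.zeros(L, dtype=bool)
    rows = {s: aln.row(s) for s in aln.sample_ids}
    for j in range(L):
        tgt = {rows[s][j] for s in tgt_ids if rows[s][j] in UNAMBIGUOUS}
        non = {rows[s][j] for s in non_ids if rows[s][j] in UNAMBIGUOUS}
        allg = {rows[s][j] for s in aln.sample_ids if rows[s][j] in UNAMBIGUOUS}
        gaps = any(rows[s][j] not in UNAMBIGUOUS for s in aln.sample_ids)
        fixed[j] = len(tgt) == 1 and bool(non) and not (tgt & non)
        intra[j] = len(tgt) > 1
        cons[j] = len(allg) == 1 and not gaps
    return SiteFlags(fixed, intra, cons)


@dataclass
class DesignWindow:
    segment: tuple[int, int]
    score: float
    fixed_positions: list[int]        # 1-based fixed-difference positions in segment
    forward_window: tuple[int, int]
    probe_window: tuple[int, int]
    reverse_window: tuple[int, int]


def _best_subwindow(score_col: np.ndarray, lo: int, hi: int, width: int) -> tuple[int, int]:
    """Leftmost max-scoring width-window with start in [lo, hi)."""
    best_start, best = lo, -np.inf
    for s in range(lo, max(hi, lo + 1)):
        sc = float(score_col[s : s + width].sum())
        if sc > best:
            best, best_start = sc, s
    return best_start, best_start + width


def snv_density_scan(
    aln: Alignment,
    table: SampleTable,
    segment_len: int = 120,
    oligo_window: int = 30,
    lam: float = 1.0,
) -> list[DesignWindow]:
    """Rank every segment placement by fixed-difference minus intra-target density.

    Within each positively scoring segment the ~30-nt oligo windows for
    forward primer / probe / reverse primer are the best local windows in the
    left / middle / right thirds.  Ordering is score descending, then leftmost.
    """
    if not (100 <= segment_len <= 150):
        raise ValueError("segment_len must lie in [100, 150]")
    if aln.L < segment_len:
        raise DesignError(f"alignment length {aln.L} < segment length {segment_len}")
    flags = site_flags(aln, table)
    col_score = flags.fixed_difference.astype(float) - lam * flags.intra_target_variable.astype(float)
    windows = []
    for s in range(aln.L - segment_len + 1):
        seg_score = float(col_score[s : s + segment_len].sum())
        if seg_score <= 0:
            continue
        third = segment_len // 3
        fw = _best_subwindow(col_score, s, s + third - oligo_window + 1, oligo_window)
        pw = _best_subwindow(col_score, s + third, s + 2 * third - oligo_window + 1, oligo_window)
        rv = _best_subwindow(col_score, s + segment_len - third, s + segment_len - oligo_window + 1, oligo_window)
        fixed_pos = [j + 1 for j in range(s, s + segment_len) if flags.fixed_difference[j]]
        windows.append(DesignWindow((s, s + segment_len), seg_score, fixed_pos, fw, pw, rv))
    if not windows:
        warnings.warn("snv_density_scan: no segment with positive score", stacklevel=2)
        return []
    windows.sort(key=lambda w: (-w.score, w.segment[0]))
    return windows


# --- candidates --------------------------------------------------------------

@dataclass
class OligoCandidate:
    sequence: str                    # 5'->3' on its own strand
    role: str                        # forward | reverse | probe
    interval: tuple[int, int]        # alignment top-strand coordinates
    tm_nn: float
    tm_salt: float | None
    gc_percent: float
    structure: StructureScores
    disc_count: int = 0
    disc_positions: list[int] = field(default_factory=list)
    end_weighted_score: float = 0.0
    closeness_penalty: float = 0.0


def _closeness(seq: str, tm: float, role: str, c: OligoConstraints) -> float:
    """Distance-to-optimum penalty used to pick the best few passing candidates."""
    tm_t, len_t = c.tm_for(role), c.len_for(role)
    return (
        abs(tm - tm_t.opt)
        + 0.1 * abs(100.0 * gc_fraction(seq) - c.gc_percent.opt)
        + 0.5 * abs(len(seq) - len_t.opt)
    )


def passes_hard_constraints(seq: str, role: str, c: OligoConstraints) -> tuple[bool, float, str]:
    """Check one oligo sequence (5'->3') against every hard constraint.

    Returns (ok, nn_tm, first_failure_reason).
    """
    tm = tm_nearest_neighbor(seq, **c.tm_args())
    tm_t = c.tm_for(role)
    if not tm_t.contains(tm):
        return False, tm, f"tm {tm:.1f} outside [{tm_t.min}, {tm_t.max}]"
    gc = 100.0 * gc_fraction(seq)
    if not c.gc_percent.contains(gc):
        return False, tm, f"gc {gc:.0f} outside [{c.gc_percent.min}, {c.gc_percent.max}]"
    scr = structure_screen(seq)
    if scr.poly_x > c.max_poly_x:
        return False, tm, f"poly-X run {scr.poly_x} > {c.max_poly_x}"
    if scr.three_prime_stability > c.max_three_prime_stability:
        return False, tm, "3' terminal pentamer too stable"
    if scr.self_dimer_tm > c.max_dimer_tm:
        return False, tm, f"self-dimer Tm {scr.self_dimer_tm:.1f} > {c.max_dimer_tm}"
    return True, tm, ""


def enumerate_candidates(
    window: tuple[int, int],
    aln: Alignment,
    table: SampleTable,
    constraints: OligoConstraints,
    role: str,
    flags: SiteFlags | None = None,
    consensus: str | None = None,
) -> list[OligoCandidate]:
    """All constraint-passing oligos within a window of the target consensus.

    Substrings of every allowed length are screened; those containing gaps or
    ambiguity codes in the consensus are skipped.  Two inclusivity constraints
    keep the assay detecting every target haplotype: primer candidates may not
    carry an intra-target variable site in their 3 terminal 3' bases, and
    probe candidates may cover at most one such site.  The best
    ``candidates_per_window`` survivors by distance-to-optimum are returned.
    """
    if role not in ("forward", "reverse", "probe"):
        raise ValueError(f"unknown role {role!r}")
    if flags is None:
        flags = site_flags(aln, table)
    if consensus is None:
        consensus = consensus_sequence(
            aln, [x for x in aln.sample_ids if table.group_of(x) == "target"]
        )
    lo, hi = window
    len_t = constraints.len_for(role)
    out = []
    for start in range(lo, hi):
        for length in range(int(len_t.min), int(len_t.max) + 1):
            end = start + length
            if end > hi:
                break
            top = consensus[start:end]
            if any(ch not in UNAMBIGUOUS for ch in top):
                continue
            seq = reverse_complement(top) if role == "reverse" else top
            # inclusivity: intra-target variants must not sit under primer 3' ends
            intra_idx = [j for j in range(start, end) if flags.intra_target_variable[j]]
            if role == "forward" and any(j >= end - 3 for j in intra_idx):
                continue
            if role == "reverse" and any(j < start + 3 for j in intra_idx):
                continue
            if role == "probe" and len(intra_idx) > 1:
                continue
            ok, tm, _ = passes_hard_constraints(seq, role, constraints)
            if not ok:
                continue
            try:
                salt = tm_salt_adjusted(seq, constraints.monovalent_molar)
            except DesignError:
                salt = None
            cand = OligoCandidate(
                sequence=seq,
                role=role,
                interval=(start, end),
                tm_nn=tm,
                tm_salt=salt,
                gc_percent=100.0 * gc_fraction(seq),
                structure=structure_screen(seq),
                closeness_penalty=_closeness(seq, tm, role, constraints),
            )
            count, pos, score = discriminative_support(cand, flags, constraints)
            cand.disc_count, cand.disc_positions, cand.end_weighted_score = count, pos, score
            out.append(cand)
    out.sort(key=lambda c: (c.closeness_penalty, c.interval))
    return out[: constraints.candidates_per_window]


def discriminative_support(
    cand: OligoCandidate, flags: SiteFlags, constraints: OligoConstraints
) -> tuple[int, list[int], float]:
    """Fixed differences under the footprint, with 2x weight near either end.

    Positions within ``end_weight_span`` bases of either end of the oligo
    footprint receive weight ``end_weight`` (variants at oligo ends
    discriminate most strongly in practice); the rest weigh 1.
    """
    start, end = cand.interval
    span = constraints.end_weight_span
    positions, score = [], 0.0
    for j in range(start, end):
        if flags.fixed_difference[j]:
            positions.append(j + 1)
            near_end = (j - start) < span or (end - 1 - j) < span
            score += constraints.end_weight if near_end else 1.0
    return len(positions), positions, score


# --- assay sets --------------------------------------------------------------

@dataclass
class AssaySet:
    forward: OligoCandidate
    reverse: OligoCandidate
    probe: OligoCandidate
    amplicon: tuple[int, int]
    total_disc: int
    end_weighted: float
    tm_differential: float            # probe Tm minus mean primer Tm
    structure_penalty: float
    rank: int = 0

    @property
    def amplicon_length(self) -> int:
        return self.amplicon[1] - self.amplicon[0]

    def oligos(self) -> list[OligoCandidate]:
        return [self.forward, self.reverse, self.probe]


def _structure_penalty(f: OligoCandidate, r: OligoCandidate, p: OligoCandidate) -> float:
    pen = 0.0
    for o in (f, r, p):
        pen += o.structure.self_dimer_tm + o.structure.hairpin_stem
    for a, b in ((f, r), (f, p), (r, p)):
        het = structure_screen(a.sequence, b.sequence)
        pen += het.hetero_dimer_tm or 0.0
    return pen


def _feasible_geometry(f: OligoCandidate, r: OligoCandidate, p: OligoCandidate) -> bool:
    return (
        f.interval[1] <= p.interval[0]
        and p.interval[1] <= r.interval[0]
        and (r.interval[1] - f.interval[0])
        >= (len(f.sequence) + len(r.sequence) + len(p.sequence))
    )


def rank_assay_sets(
    forwards: list[OligoCandidate],
    reverses: list[OligoCandidate],
    probes: list[OligoCandidate],
    constraints: OligoConstraints,
    require_terminal_disc: bool = True,
) -> list[AssaySet]:
    """Rank feasible F/R/P triples.

    Feasibility: non-overlapping footprints in F < P < R order, probe NN Tm
    above both primer Tms, and (by default) each primer carrying at least one
    fixed difference in its 3 terminal 3' bases — the end-located variants
    that make a mismatch abort extension in every nontarget.  Ranking is
    lexicographic: total discriminative count desc, end-weighted score desc,
    probe-minus-mean-primer Tm differential desc, aggregate structure penalty
    asc, then coordinates.  Empty input or no feasible triple returns []
    (diagnostics via the returned reasons list of ``assay_diagnostics``).
    """
    sets = []
    for f in forwards:
        for r in reverses:
            for p in probes:
                if not _feasible_geometry(f, r, p):
                    continue
                if not (p.tm_nn > f.tm_nn and p.tm_nn > r.tm_nn):
                    continue
                if require_terminal_disc:
                    fe = f.interval[1]
                    if not any(pos - 1 >= fe - 3 for pos in f.disc_positions):
                        continue
                    rs = r.interval[0]
                    if not any(pos - 1 < rs + 3 for pos in r.disc_positions):
                        continue
                total = f.disc_count + r.disc_count + p.disc_count
                endw = f.end_weighted_score + r.end_weighted_score + p.end_weighted_score
                tmdiff = p.tm_nn - 0.5 * (f.tm_nn + r.tm_nn)
                sets.append(
                    AssaySet(
                        forward=f, reverse=r, probe=p,
                        amplicon=(f.interval[0], r.interval[1]),
                        total_disc=total, end_weighted=endw,
                        tm_differential=tmdiff,
                        structure_penalty=_structure_penalty(f, r, p),
                    )
                )
    sets.sort(
        key=lambda a: (
            -a.total_disc, -a.end_weighted, -a.tm_differential,
            a.structure_penalty, a.forward.interval, a.reverse.interval, a.probe.interval,
            a.forward.sequence, a.reverse.sequence, a.probe.sequence,
            a.forward.tm_nn, a.reverse.tm_nn, a.probe.tm_nn,
        )
    )
    for i, a in enumerate(sets):
        a.rank = i + 1
    return sets


def assay_diagnostics(
    forwards: list[OligoCandidate],
    reverses: list[OligoCandidate],
    probes: list[OligoCandidate],
) -> list[str]:
    reasons = []
    if not forwards:
        reasons.append("no passing forward-primer candidate")
    if not reverses:
        reasons.append("no passing reverse-primer candidate")
    if not probes:
        reasons.append("no passing probe candidate")
    if forwards and reverses and probes:
        reasons.append("candidates exist but no triple satisfied geometry/Tm ordering")
    return reasons


def design_assay(
    aln: Alignment,
    table: SampleTable,
    constraints: OligoConstraints | None = None,
    segment_len: int = 120,
    oligo_window: int = 30,
    lam: float = 1.0,
    max_segments: int = 5,
) -> list[AssaySet]:
    """End-to-end diagnostic design: scan, enumerate per window, rank triples."""
    constraints = constraints or OligoConstraints()
    flags = site_flags(aln, table)
    consensus = consensus_sequence(
            aln, [x for x in aln.sample_ids if table.group_of(x) == "target"]
        )
    ranked = []
    for win in snv_density_scan(aln, table, segment_len, oligo_window, lam)[:max_segments]:
        fs = enumerate_candidates(win.forward_window, aln, table, constraints, "forward", flags, consensus)
        rs = enumerate_candidates(win.reverse_window, aln, table, constraints, "reverse", flags, consensus)
        ps = enumerate_candidates(win.probe_window, aln, table, constraints, "probe", flags, consensus)
        ranked.extend(rank_assay_sets(fs, rs, ps, constraints))
    ranked.sort(
        key=lambda a: (
            -a.total_disc, -a.end_weighted, -a.tm_differential, a.structure_penalty,
            a.forward.interval, a.reverse.interval, a.probe.interval,
            a.forward.sequence, a.reverse.sequence, a.probe.sequence,
            a.forward.tm_nn, a.reverse.tm_nn, a.probe.tm_nn,
        )
    )
    for i, a in enumerate(ranked):
        a.rank = i + 1
    return ranked


# --- control assay -----------------------------------------------------------

def design_control_assay(
    aln: Alignment,
    table: SampleTable,
    diagnostic: AssaySet,
    constraints: OligoConstraints | None = None,
) -> AssaySet:
    """Design a control assay inside a fully conserved block, Tm-capped by the diagnostic.

    Window selection inverts the diagnostic criterion: conservation across
    every sample is maximized (the control must amplify everything), and the
    selected control oligos must not exceed the Tm of their diagnostic
    counterparts.  Raises when no invariant block can geometrically hold
    forward + probe + reverse oligos.
    """
    constraints = constraints or OligoConstraints()
    flags = site_flags(aln, table)
    consensus = consensus_sequence(aln, list(aln.sample_ids))
    # each third of the block must hold its oligo role
    need = int(3 * max(constraints.primer_len.min, constraints.probe_len.min))
    runs = []
    start = None
    for j in range(aln.L + 1):
        ok = j < aln.L and flags.conserved_all[j]
        if ok and start is None:
            start = j
        elif not ok and start is not None:
            runs.append((start, j))
            start = None
    runs = [r for r in runs if r[1] - r[0] >= need]
    if not runs:
        raise DesignError(
            "no fully conserved window large enough for a control assay; "
            "consider relaxing the conservation threshold or supplying a conserved locus"
        )
    runs.sort(key=lambda r: (-(r[1] - r[0]), r[0]))
    no_flags = SiteFlags(
        np.zeros(aln.L, dtype=bool), np.zeros(aln.L, dtype=bool), flags.conserved_all
    )
    for lo, hi in runs:
        width = hi - lo
        third = width // 3
        fs = enumerate_candidates((lo, lo + third), aln, table, constraints, "forward", no_flags, consensus)
        ps = enumerate_candidates((lo + third, lo + 2 * third), aln, table, constraints, "probe", no_flags, consensus)
        rs = enumerate_candidates((lo + 2 * third, hi), aln, table, constraints, "reverse", no_flags, consensus)
        fs = [c for c in fs if c.tm_nn <= diagnostic.forward.tm_nn]
        rs = [c for c in rs if c.tm_nn <= diagnostic.reverse.tm_nn]
        ps = [c for c in ps if c.tm_nn <= diagnostic.probe.tm_nn]
        sets = rank_assay_sets(fs, rs, ps, constraints, require_terminal_disc=False)
        if sets:
            best = sets[0]
            best.rank = 1
            return best
    raise DesignError(
        "conserved blocks exist but no control triple passed constraints under "
        "the diagnostic Tm cap; consider relaxing the conservation threshold"
    )


# --- in-silico specificity ---------------------------------------------------

def _footprint_mismatches(sample_row: str, oligo: OligoCandidate) -> tuple[int, int]:
    """(total mismatches, mismatches in the 3 terminal 3' bases) for one sample.

    The oligo's top-strand footprint is compared column-wise; a gap counts as
    a mismatch, an ambiguity code matches when the oligo base is among its
    expansion.
    """
    from .alignment import IUPAC_TO_BASES

    start, end = oligo.interval
    top = reverse_complement(oligo.sequence) if oligo.role == "reverse" else oligo.sequence
    total = 0
    term3 = 0
    for k, j in enumerate(range(start, end)):
        call = sample_row[j]
        ob = top[k]
        if call in UNAMBIGUOUS:
            mm = call != ob
        elif call == "-":
            mm = True
        else:
            mm = ob not in IUPAC_TO_BASES.get(call, set())
        if mm:
            total += 1
            if oligo.role == "forward" and j >= end - 3:
                term3 += 1
            if oligo.role == "reverse" and j < start + 3:
                term3 += 1
    return total, term3


def in_silico_specificity(
    assay: AssaySet, panel: Alignment, table: SampleTable,
    max_primer_mismatches: int = 2, max_probe_mismatches: int = 1,
) -> pd.DataFrame:
    """Predict per-sample amplification from footprint mismatch counts.

    Amplification is predicted when each primer has at most
    ``max_primer_mismatches`` total mismatches and none in its 3 terminal 3'
    bases, and the probe has at most ``max_probe_mismatches``.
    """
    for o in assay.oligos():
        if o.interval[1] > panel.L:
            raise DesignError(
                f"{o.role} footprint {o.interval} outside panel coordinates (L={panel.L})"
            )
    rows = []
    for sid in panel.sample_ids:
        row = panel.row(sid)
        f_mm, f_t3 = _footprint_mismatches(row, assay.forward)
        r_mm, r_t3 = _footprint_mismatches(row, assay.reverse)
        p_mm, _ = _footprint_mismatches(row, assay.probe)
        predicted = (
            f_mm <= max_primer_mismatches and f_t3 == 0
            and r_mm <= max_primer_mismatches and r_t3 == 0
            and p_mm <= max_probe_mismatches
        )
        rows.append(
            {
                "sample_id": sid,
                "group": table.group_of(sid) if sid in table else "",
                "forward_mismatches": f_mm, "forward_3prime_mismatches": f_t3,
                "reverse_mismatches": r_mm, "reverse_3prime_mismatches": r_t3,
                "probe_mismatches": p_mm,
                "predicted_amplification": predicted,
            }
        )
    return pd.DataFrame(rows)


def assay_report(assays: list[AssaySet]) -> pd.DataFrame:
    """Flat TSV-ready report of ranked assay sets."""
    rows = []
    for a in assays:
        for o in a.oligos():
            rows.append(
                {
                    "rank": a.rank,
                    "role": o.role,
                    "sequence": o.sequence,
                    "start_1based": o.interval[0] + 1,
                    "end_1based": o.interval[1],
                    "tm_nn": round(o.tm_nn, 2),
                    "tm_salt": o.tm_salt,
                    "gc_percent": round(o.gc_percent, 1),
                    "disc_count": o.disc_count,
                    "end_weighted": o.end_weighted_score,
                    "self_dimer_tm": round(o.structure.self_dimer_tm, 1),
                    "hairpin_stem": o.structure.hairpin_stem,
                    "poly_x": o.structure.poly_x,
                    "amplicon_length": a.amplicon_length,
                    "total_disc": a.total_disc,
                    "tm_differential": round(a.tm_differential, 2),
                }
            )
    return pd.DataFrame(rows)
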