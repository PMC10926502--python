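"""Oligo melting temperatures and structure screens.

Two deliberately separate Tm engines:

``tm_salt_adjusted``
    The salt-adjusted GC-content formula used to recalculate the published
    primer Tm values:  Tm = 100.5 + 41*(nGC/N) - 820/N + 16.6*log10([Na+]),
    evaluated at 50 mM monovalent salt and reported to one decimal.

``tm_nearest_neighbor``
    The unified nearest-neighbor model (SantaLucia 1998, PNAS 95:1460; stack
    parameters identical to Allawi & SantaLucia 1997, Biochemistry 36:10581)
    used for design-constraint checks:

        Tm(K) = dH * 1000 / (dS + R * ln(CT / x))

    with R = 1.987 cal/(K*mol), x = 1 for self-complementary duplexes (with
    the symmetry entropy term) and x = 4 otherwise, followed by the entropy
    salt correction dS += 0.368*(N-1)*ln[Na+_eq] where the divalent/dNTP
    monovalent-equivalent is [Na+_eq] (mM) = mono + 120*sqrt(Mg - dNTP)
    (von Ahsen et al. 2001, Clin Chem 47:1956).

Structure screens (self/hetero-dimer, hairpin, self-annealing, poly-X runs,
3'-terminal pentamer stability) are exhaustive over ungapped offsets, which
is exact at primer scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DesignError

R_CAL = 1.987  # cal / (K * mol)

COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Unified NN parameters: dH (kcal/mol), dS (cal/(K*mol)) per 5'->3' stack.
NN_PARAMS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
INIT_GC = (0.1, -2.8)    # initiation with a terminal G.C pair
INIT_AT = (2.3, 4.1)     # initiation with a terminal A.T pair
SYMMETRY_DS = -1.4       # self-complementary entropy penalty


def _check_plain(seq: str, min_len: int, op: str) -> str:
    seq = seq.upper()
    if len(seq) < min_len:
        raise DesignError(f"{op}: sequence shorter than {min_len} nt")
    bad = set(seq) - set("ACGT")
    if bad:
        raise DesignError(f"{op}: ambiguous or illegal characters {sorted(bad)}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return (seq.count("G") + seq.count("C")) / len(seq)


def tm_salt_adjusted(seq: str, na_molar: float = 0.05) -> float:
    """Salt-adjusted GC-formula Tm in deg C, rounded to one decimal."""
    seq = _check_plain(seq, 8, "tm_salt_adjusted")
    if na_molar <= 0:
        raise ValueError("monovalent salt concentration must be positive")
    n = len(seq)
    ngc = seq.count("G") + seq.count("C")
    tm = 100.5 + 41.0 * (ngc / n) - 820.0 / n + 16.6 * math.log10(na_molar)
    return round(tm, 1)


def is_self_complementary(seq: str) -> bool:
    return seq.upper() == reverse_complement(seq)


def nn_sums(seq: str) -> tuple[float, float]:
    """Total dH (kcal/mol) and dS (cal/K/mol) including initiation and symmetry terms."""
    seq = _check_plain(seq, 2, "nn_sums")
    dh, ds = 0.0, 0.0
    for a, b in zip(seq, seq[1:]):
        h, s = NN_PARAMS[a + b]
        dh += h
        ds += s
    for end in (seq[0], seq[-1]):
        h, s = INIT_GC if end in "GC" else INIT_AT
        dh += h
        ds += s
    if is_self_complementary(seq):
        ds += SYMMETRY_DS
    return dh, ds


def delta_g37(seq: str) -> float:
    """Duplex dG at 37 C in kcal/mol (dG = dH - T*dS)."""
    dh, ds = nn_sums(seq)
    return dh - 310.15 * ds / 1000.0


def monovalent_equivalent(
    na_molar: float, mg_molar: float = 0.0, dntp_molar: float = 0.0
) -> float:
    """Monovalent-equivalent salt (molar): Na + 120*sqrt(Mg - dNTP) in mM units."""
    na_mm = na_molar * 1000.0
    mg_mm = max(mg_molar - dntp_molar, 0.0) * 1000.0
    return (na_mm + 120.0 * math.sqrt(mg_mm)) / 1000.0


def tm_nearest_neighbor(
    seq: str,
    na_molar: float = 0.05,
    mg_molar: float = 0.0015,
    dntp_molar: float = 0.0006,
    strand_molar: float = 5e-8,
) -> float:
    """Unified nearest-neighbor Tm in deg C under the stated buffer conditions.

    ``strand_molar`` is the total oligo strand concentration CT; the effective
    concentration term is CT/4 for non-self-complementary duplexes (equal
    strand mix) and CT for self-complementary ones.
    """
    seq = _check_plain(seq, 2, "tm_nearest_neighbor")
    if strand_molar <= 0:
        raise ValueError("strand concentration must be positive")
    dh, ds = nn_sums(seq)
    na_eq = monovalent_equivalent(na_molar, mg_molar, dntp_molar)
    if na_eq <= 0:
        raise ValueError("effective salt concentration must be positive")
    ds = ds + 0.368 * (len(seq) - 1) * math.log(na_eq)
    x = 1.0 if is_self_complementary(seq) else 4.0
    tm_k = dh * 1000.0 / (ds + R_CAL * math.log(strand_molar / x))
    return tm_k - 273.15


# --- structure screens -------------------------------------------------------

@dataclass
class StructureScores:
    self_annealing: int          # max complementary pairings over all offsets
    self_dimer_tm: float         # NN Tm (deg C, floored at 0) of best self-dimer stretch
    hairpin_stem: int            # longest intramolecular stem with loop >= 3
    poly_x: int                  # longest single-base run
    three_prime_stability: float # |dG37| of the 5 terminal 3' bases
    hetero_dimer_tm: float | None = None
    hetero_annealing: int | None = None


def _duplex_runs(a: str, b: str):
    """Yield (score, best_run_subseq) per antiparallel offset of a vs b.

    ``a`` 5'->3' is paired against ``b`` 3'->5' (i.e. reversed), Watson-Crick
    matches only, ungapped.
    """
    brev = b[::-1]
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for off in range(-(len(brev) - 1), len(a)):
        score = 0
        best_run = ""
        run_start = None
        i = max(0, off)
        while i < len(a) and i - off < len(brev):
            if comp[a[i]] == brev[i - off]:
                score += 1
                if run_start is None:
                    run_start = i
                if i - run_start + 1 > len(best_run):
                    best_run = a[run_start : i + 1]
            else:
                run_start = None
            i += 1
        yield score, best_run


def _best_dimer(a: str, b: str) -> tuple[int, float]:
    """Max annealing score and best NN duplex Tm over all ungapped offsets."""
    best_score = 0
    best_tm = 0.0
    for score, run in _duplex_runs(a, b):
        best_score = max(best_score, score)
        if len(run) >= 2:
            tm = tm_nearest_neighbor(run)
            best_tm = max(best_tm, tm)
    return best_score, max(best_tm, 0.0)


def longest_hairpin_stem(seq: str, min_loop: int = 3) -> int:
    """Longest perfect intramolecular stem closable with a loop >= min_loop."""
    n = len(seq)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    best = 0
    for i in range(n):
        for j in range(n - 1, i + min_loop, -1):
            k = 0
            while i + k < j - k and (j - k) - (i + k) - 1 >= min_loop and comp[seq[i + k]] == seq[j - k]:
                k += 1
            best = max(best, k)
    return best


def longest_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def structure_screen(oligo: str, partner: str | None = None) -> StructureScores:
    """Exhaustive-offset structure screen of one oligo (optionally vs a partner)."""
    oligo = _check_plain(oligo, 2, "structure_screen")
    ann, dimer_tm = _best_dimer(oligo, oligo)
    scores = StructureScores(
        self_annealing=ann,
        self_dimer_tm=dimer_tm,
        hairpin_stem=longest_hairpin_stem(oligo),
        poly_x=longest_run(oligo),
        three_prime_stability=abs(delta_g37(oligo[-5:])) if len(oligo) >= 5 else abs(delta_g37(oligo)),
    )
    if partner is not None:
        partner = _check_plain(partner, 2, "structure_screen partner")
        h_ann, h_tm = _best_dimer(oligo, partner)
        scores.hetero_dimer_tm = h_tm
        scores.hetero_annealing = h_ann
    return scores
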