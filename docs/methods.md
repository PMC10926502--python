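# Methods

`barcodedx` implements a desk-scale version of a DNA-barcode diagnostic
pipeline for the spotted cucumber beetle (*Diabrotica undecimpunctata*):
lineage delimitation from aligned CO1 barcodes, and design plus
interpretation of a duplex TaqMan real-time PCR assay that detects the main
haplogroup while excluding congeners.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not demonstrate.

## Alignment handling and site classification

The substrate is an aligned IUPAC multi-FASTA plus a sample table labeling
every sequence `target`, `nontarget` or `outgroup`.  Trimming to an
"overlapping core" removes columns whose non-gap fraction falls below
`min_nongap_fraction` (default 0.7) and then sequences spanning less than
`min_span_fraction` (default 0.8) of the surviving columns; because row
removal can re-expose gappy columns, the pass repeats to a fixpoint, making
the operation idempotent.  The defaults are conventional coverage thresholds,
not claimed to reproduce any particular published matrix dimension.

Haplotypes are defined by exact string identity — ambiguity codes and gaps
are ordinary characters, so an `N`-bearing sequence is its own haplotype.
This keeps collapsing reproducible and order-independent; degraded museum
material therefore inflates haplotype counts rather than silently merging
uncertain calls.

Per-column classification distinguishes *fixed differences* (all targets
share a state no nontarget carries), *autapomorphies* (a minority state
carried only by samples with one identical full-length sequence, so
duplicated specimens do not erase it), and *shared-ancestral* states (all
targets matching the outgroup while nontargets differ).  Columns containing
any gap or ambiguity are classified from their unambiguous calls but flagged
low-confidence.

Consensus calling is plurality-based (threshold 0.5 by default) over
unambiguous non-gap calls; a tied or sub-threshold column gets the minimal
IUPAC code covering all bases at ≥ 25% frequency.

## Distances, trees, support

Pairwise distances use the Tamura–Nei (TN93) closed form, separating the two
transition classes (A↔G proportion P1, C↔T proportion P2) from transversions
(Q) with empirical base frequencies pooled per pair (alignment-wide pooling
is available).  Sites with a gap or ambiguity in either sequence are deleted
pairwise.  A non-positive logarithm argument marks the pair *saturated*; such
entries carry a flag instead of a number, and tree building refuses matrices
containing them rather than guessing.

Neighbor joining is the standard Saitou–Nei agglomeration with two
documented determinism rules: Q-criterion ties break toward the lowest pair
of original label indices, and negative branch lengths are clamped to zero
with the deficit moved to the sister branch (preserving path lengths through
the join).  NJ is exact on additive matrices, which the suite verifies on
100 random 6–10-leaf trees.

Branch support comes from delete-half jackknifing: each replicate deletes
⌈0.5·L⌉ columns without replacement, rebuilds TN93+NJ, and internal edges of
the full-data tree are annotated with the percentage of successful replicates
recovering their bipartition.  The 0.5 deletion fraction is the common
delete-half convention and is configurable; replicates whose subsampled
matrix is saturated are skipped and excluded from the denominator.  Support
values are deterministic given a seed; they are invariant to column order
only in distribution (exactly so for splits carried by many fixed
differences), since any column-index resampler ties its draws to positions.

## Statistical-parsimony networks

Haplotypes are joined in nondecreasing step order (Hamming distance over
columns where both calls are unambiguous), never closing a cycle, up to the
parsimony connection limit; multi-step connections pass through abstract,
sequence-free intermediate nodes so every edge is one mutational step.  With
`force_connect` (default on), residual components join through their minimum
inter-component pair, flagged `forced` — this mirrors network software that
draws long connections past the confidence limit, and it never alters paths
among already-connected nodes.

The connection limit is the largest step count j whose "probability of
parsimony" stays at or above the confidence level (default 0.95).  We compute
that probability from the generative model underlying statistical parsimony:
mutations strike sites uniformly along L comparable sites, each changing the
base to one of three alternatives, so the number of visibly different sites
D follows a Markov chain in the number of mutations M (up (L−D)/L, down
(D/L)/3, stay (D/L)·2/3).  The probability that j observed differences arose
from exactly j mutations is taken as P(M=j | D=j) under a flat prior on M,
truncated at M = j + 60 where the terms are numerically negligible.  The
chain is validated against a Monte-Carlo simulation of the raw mutation
process.  This operationalization is deliberately conservative relative to
classic network software (it yields a limit of 5 steps at L=420 and 95%);
since the limit only decides which connections are flagged as forced, none
of the reported step metrics depend on it.

A practical byproduct: the *parsimony component* of the modal haplotype —
everything reachable without forced edges — is how the pipeline delimits the
focal haplogroup.  On the synthetic data this recovers exactly the planted
main group, excluding the 20-step outlier lineage and all congeners.

## Melting temperatures

Two engines, kept separate because they answer different questions:

- **Salt-adjusted GC formula** (reporting):
  Tm = 100.5 + 41·(nGC/N) − 820/N + 16.6·log10([Na+]), evaluated at 50 mM
  monovalent salt and rounded to one decimal.  This formula reproduces the
  published Tm values of the five legacy PCR primers to the printed decimal,
  which is why it is the reporting engine.
- **Unified nearest-neighbor model** (design constraints): stack ΔH/ΔS sums
  from the unified parameter set (SantaLucia 1998; identical to Allawi &
  SantaLucia 1997), initiation terms by terminal pair, symmetry entropy
  −1.4 cal/(K·mol) for self-complementary oligos, Tm(K) = ΔH·1000/(ΔS +
  R·ln(CT/x)) with x = 4 for heteroduplex-at-equal-strands and x = 1 for
  self-complementary oligos, then the entropy salt correction
  ΔS += 0.368·(N−1)·ln[Na+eq] with the divalent/dNTP monovalent equivalent
  [Na+eq] (mM) = mono + 120·√(Mg − dNTP) (von Ahsen et al. 2001).  Default
  buffer: 50 mM monovalent, 1.5 mM Mg, 0.6 mM dNTP, 50 nM total strands.
  The implementation agrees with Biopython's independent `Tm_NN` to 1e-6 °C.

Structure screens (self-dimer, hetero-dimer, self-annealing, hairpin,
poly-X, 3′-terminal pentamer ΔG) are exhaustive over ungapped antiparallel
offsets — exact at oligo scale.  Dimer stretches are scored by the NN Tm of
the longest perfectly paired run (floored at 0 °C).

## Assay design

Window scanning scores every 100–150-nt segment placement (default 120) as
(fixed target/nontarget differences) − λ·(intra-target variable sites), with
λ = 1 by default; within each positive segment the ~30-nt forward / probe /
reverse oligo windows are the best local windows in its left / middle /
right thirds.  Ordering is score-descending then leftmost, and matches an
exhaustive scan by construction.

Candidate oligos are every substring of the target-group consensus within
the role's length bounds that passes the hard constraint set (primer Tm
50/55.5/60 °C, probe Tm 57/60/63 °C, GC 20–80%, primer length 14–35,
probe length 18–36, poly-X ≤ 5, 3′-pentamer |ΔG| ≤ 9 kcal/mol, self-dimer
Tm ≤ 47 °C).  Two inclusivity constraints are added so the assay detects
every target haplotype: primers may not carry an intra-target variable site
in their 3 terminal 3′ bases, and probes may cover at most one such site.
The five survivors closest to the optima (|ΔTm| + 0.1·|ΔGC| + 0.5·|Δlen|)
are kept per window.

Triples are ranked lexicographically: total discriminative count (fixed
differences under the three footprints) descending; end-weighted score
descending (positions within 5 bases of either oligo end weigh 2 —
end-located variants discriminate most strongly); probe-minus-mean-primer Tm
differential descending; aggregate structure penalty ascending; coordinates
and sequences as final tie-breaks so the order is total and
permutation-invariant.  Feasibility requires non-overlapping F < P < R
geometry, probe Tm above both primers, and each primer carrying at least one
fixed difference in its 3 terminal 3′ bases — the quantified form of
"variants at oligo ends preferred", and the property that makes every
nontarget fail the 3′-match rule by construction.

The control assay inverts the criterion: oligos are designed inside a block
conserved across *every* sample (each third of the block hosting one role),
with each control oligo capped at its diagnostic counterpart's Tm.  Real
pipelines run this on a conserved locus such as 18S rRNA; the synthetic
control locus emulates that.

In-silico specificity replaces a database search with mismatch counting on a
coordinate-shared panel: predicted amplification requires each primer to
have ≤ 2 total mismatches and none in its 3 terminal 3′ bases, and the probe
≤ 1 mismatch.  Gaps count as mismatches; sample ambiguity codes match when
the oligo base is in their expansion.

## qPCR interpretation

A channel is amplified-positive when end RFU reaches its threshold
(diagnostic 500, control 250) and Cq lies in [5, 30].  Calls: *positive* =
both channels amplified-positive with |ΔCq| ≤ 7; *anomalous* = diagnostic Cq
below the window while control Cq is above it (the copy-number-imbalance
pattern that warrants a singleplex rerun), or both channels amplifying with
|ΔCq| beyond the cutoff, or diagnostic-positive with control dropout;
*negative* = control-only; *failed* = neither.  The four calls are total and
mutually exclusive over the entire input space (property-tested by
enumeration), every call carries its reasons, and raising the ΔCq cutoff can
never demote a positive.

Standard curves fit Cq on log10(concentration) by least squares; efficiency
is E = 10^(−1/slope) − 1 (a slope of −1/log10 2 ≈ −3.3219 is exactly 100%).
The detection floor is the lowest concentration from which every
concentration upward amplified in all replicates.  Run summaries report
per-channel min/max/mean/sample-SD (n−1; a single observation reports 0 with
a flag) over amplified wells, and a suggested RFU threshold of half the 5th
percentile of amplified end-RFU rounded to the nearest 50 — a conservative
floor well under the observed signal cloud.

## Synthetic data: what it emulates and what it does not

The barcode generator plants a known genealogy with **no homoplasy** (every
mutation hits a fresh column) and **no unsampled ancestors** (every lineage
descends from a sampled haplotype).  Defaults, chosen to encode the
population structure the downstream statistics describe: a 420-nt alignment;
a main haplogroup of one 60-member center plus 12 one-step and 1 two-step
satellites of 1–5 members (14 variable positions; diameter 3); a two-member
outlier haplotype 20 steps from the center; three nontarget pseudo-species
on a nested chain at 40/45/60 steps from the center (the 40 shared chain-stem
mutations are exactly the target/nontarget fixed differences); one outgroup
at 80 steps.  Inter-lineage mutations fall preferentially (65%) inside a
130-column "divergent tract", emulating the locally SNV-dense regions that
make window scanning productive on real barcodes; main-group, outlier and
outgroup mutations fall uniformly.  Subspecies labels are assigned
round-robin over main-group members, deliberately independent of haplotype
identity (chi-square property test).  Under these guarantees the parsimony
network is the planted tree and every path step count equals the Hamming
distance — which is what makes the recovered statistics (20 steps, diameter
3, 14 variants) construction-exact rather than estimates.

The generator does **not** emulate rate heterogeneity, homoplasy, indels,
alignment error or chimeric/contaminated reads; passing tests therefore
demonstrate the pipeline's bookkeeping and decision rules, not robustness of
statistical parsimony on saturated real data.

The qPCR generator draws wells per truth class from the validated assay's
observed distributions (diagnostic Cq ~ N(15.71, 4.38) truncated to [5, 30];
ΔCq magnitude ~ |N(1.50, 0.65)| clamped under the cutoff; diagnostic RFU ~
N(1359.33, 209.07) floored just above threshold; control RFU ~ N(1533.68,
546.79); anomalous wells uniform in the reported 1.6–5 / 32.9–37.1 Cq
ranges).  Truncation and flooring keep each class inside its defining call
rule, so generator + classifier closure is testable; this is a simulation
convenience, not a claim about assay biology.  Default class counts
(106/4/5/1) mirror a realistic panel composition.  The dilution-series
generator responds linearly in Cq with slope −1/log10 2, 0.15-cycle noise,
and 50% per-replicate dropout below 0.1 ng/µL.

## Problem sizes and runtime choices

The analysis drivers run the jackknife on haplotype representatives (19
nodes, 300 replicates) rather than all samples — identical topology, since
duplicate sequences add zero-length cherries.  Property suites use 6–10-leaf
trees and ≤ 40-nt enumeration windows, where brute-force oracles are exact.

## Known limitations

- The parsimony-limit probability model is this package's own derivation;
  its absolute limits sit below those of classic TCS-style software, though
  ordering and monotonicity agree.
- NJ resolves the star-like multifurcation at the haplogroup center
  arbitrarily (tie rule); species-level monophyly flags on star data can be
  False for purely tie-resolution reasons.
- The channel naming follows the published oligo table (diagnostic = FAM CO1
  probe, control = Cy5 18S probe); one prose passage in the source
  literature assigns the fluorophores oppositely, and the table was taken as
  authoritative.
- Mismatch-based specificity prediction is a screen, not a hybridization
  model; it ignores position-dependent mismatch thermodynamics beyond the 3′
  rule.
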