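# Methods

## Coverage model

The coverage engine treats the target genome as a circle of circumference
*L*. Each of the *R* community reads is independently on-target with
probability α; an on-target read covers an arc of length *l* whose start is
uniform on the circle. *B* counts the maximal uncovered intervals of the
resulting ideal assembly (the hypothetical assembly in which overlapping
reads always merge). Under this model the gap-count probability

P(B=k) = C(R,k) Σ_{β=k}^{η} C(R−k, β−k) (−1)^{β−k} α^β (1−βφ)^{β−1} (1−βφα)^{R−β},
φ = l/L,

is exact; we verified this by exhaustive enumeration at small R (the worked
constants 0.2, 0.8, 0.30, 0.70 in the tests) and by an independent
Monte-Carlo simulator of the same generative process (`metacover.oracle`).
At α = 1 the expression collapses algebraically to Stevens' classical
circle-covering series Σ (−1)^β C(R,β)(1−βφ)^{R−1}, which the tests evaluate
independently at fixed 512-bit precision as a cross-check.

### The series limiter

The inclusion–exclusion index must stop at the last β with 1 − βφ **strictly**
positive: η = min(R, ⌈1/φ⌉ − 1) when 1/φ is an integer, else min(R, ⌊1/φ⌋).
An inclusive cutoff at integer 1/φ would introduce a 0^{β−1} factor and, at
φ = 1, the absurd conclusion that a genome-spanning read never covers the
genome. The boundary decision is made in exact rational arithmetic
(`fractions.Fraction`), so no floating-point rounding can flip it. The β = 0
term is defined as 1 (its (1−0)^{−1} factor is 1); no other degenerate powers
arise under the strict limiter.

### Degenerate inputs

- R = 0 → P(B=0) = 1: an empty assembly has no gaps.
- φ ≥ 1 → η = 0 and P(B=0) = 1 for every R and α.
- k above η → exactly 0 (more than η disjoint uncovered intervals cannot fit).
- Non-integer l and L are accepted — only their ratio enters the series —
  while R and k must be integers.

### The B = 0 convention and its planner consequence

P(B=0) includes the event that zero reads are on-target. This makes the
full-coverage probability **non-monotone in R at small α**: one likely-absent
target is "trivially covered", and adding a few reads first *lowers* P(B=0)
before coverage proper takes over. Consequently the planner can declare a
very rare target "covered" at a high threshold simply because it is probably
unsequenced (e.g. α = 0.001 gives P ≥ 0.999 after a single read). We report
the raw series value rather than subtracting the null event, because the
conditional quantity would no longer match the series the engine implements;
users planning for rare targets should read the per-run probability table,
not only the stopping run. Monotonicity in R and in φ holds at α = 1 and is
asserted in the tests only there.

## Arbitrary-precision evaluation

The series alternates with intermediate terms up to ~C(R, η)·α^η, which for
R = 10⁷ dwarfs the final probability by hundreds of orders of magnitude.
`evaluate_stable` sums the terms with mpmath at a working precision of p
bits (binomials are computed exactly as Python integers and rounded once),
then doubles p and re-evaluates until two successive evaluations agree to
rel_tol = 10⁻¹² (or both fall below 10⁻³⁰⁰, where relative agreement is
meaningless). Defaults: start at 128 bits, ceiling 1 048 576 bits. Hitting
the ceiling raises `NonConvergenceError` carrying both estimates — never a
silent wrong value. Accepted values may overshoot [0, 1] by at most 10⁻¹²
and are clamped; larger excursions are treated as evaluation failures.

## Monte-Carlo oracle

`simulate_gap_counts` draws the generative model directly with continuous
(real-valued) positions. Gap counting uses the equal-arc-length shortcut:
after sorting the on-target starts, a gap exists between consecutive arcs
(including the wrap-around) iff their spacing strictly exceeds the arc
length — exact for equal arcs, because no arc can extend past the end of a
later-starting one. Exact-touch endpoints count as covered (a measure-zero
event in the continuous model). Trials with zero on-target reads tally as
B = 0, mirroring the analytic convention. The validation grid
(R ∈ {1,2,3,5,10} × φ ∈ {0.3,0.6,0.9} × α ∈ {0.25,0.5,1.0}, 2·10⁵ trials
per cell, agreement within 4 binomial standard errors for k ≤ 3) runs in a
few seconds vectorised over trials; with 153 four-sigma checks per sweep, an
occasional single marginal excursion is statistically expected.

## Run planner

Runs are additive in reads and nothing else: after n runs the engine
evaluates P(B=0) at R = n·reads_per_run with the profile's mean read length.
The planner stops at the first n ≤ 10 reaching the threshold (default 0.95,
exposed as a flag) or reports all ten probabilities with a not-reached
verdict. Ten runs is a planning horizon, not a numerical limit: a design
that fails at ten runs needs a different platform or enrichment, not more
iterations.

## Sequencing profiles

A profile stores reads_per_run, read-length mean and standard deviation
(SD is the dispersion measure), max_length, and the mean phred-implied error
probability 10^(−Q/10) at each position, averaged over the reads that reach
that position. Averaging probabilities rather than phred scores preserves
the expected error *rate*, which is what the simulator reproduces (the mean
of 0.1 and 0.01 is 0.055, not the 10^(−1.5) ≈ 0.032 implied by the mean
score). Profiles serialise as flat JSON with full float precision, so
save → load is the identity.

Seven platform presets (IonTorrent, IonProton, Illumina MiSeq/HiSeq/NextSeq,
PacBio, Oxford Nanopore) are constructed from compact parametric error
curves (geometric ramp from a start to an end error rate across the read).
Their read-length regimes and raw error magnitudes are representative of the
platforms' published characteristics, not measurements of any particular
run; they are intended as editable starting points (`save_profile` writes
any preset to JSON) and only their structural invariants are asserted in
tests. Infer a profile from your own FASTQ for quantitative work.

## Read simulator

Per read: species multinomial in the community weights (uniform, or
exponential in rank with decay rate 0.5 by default); length from a rounded
Normal(length_mean, length_sd) truncated to [1, min(max_length, genome
length)]; start uniform over the linear genome; strand uniform, with the
minus strand reverse-complemented. Substitution errors are injected
independently per position at the profile's error probability; an error
replaces the base with a uniformly chosen different nucleotide and is
written in lowercase, so the FASTQ alone carries the error positions.
Qualities are Q_j = clamp(round(−10 log₁₀ error_j), 2, 41), Sanger phred+33.
The key CSV (header `read_id,genome_id,start,end,strand,n_errors`, 0-based
half-open forward-strand coordinates) is written alongside; read-id sets in
the two files are identical, and re-substituting the genome base at each
lowercase position reconstructs the source substring exactly — asserted for
every read in the acceptance suite.

Deliberate simplifications, and what passing tests do not show about real
data: substitution-only errors (indels would break the position-preserving
lowercase convention), single-end reads from both strands, no GC or
amplification bias, no duplicate or chimeric reads, i.i.d. synthetic genomes
in the test fixtures (no repeats), and linear read placement while the
coverage theory assumes a circle — a mismatch of order l/L at genome ends
that is negligible for short reads on viral genomes but means simulator
output should not be used to validate the coverage series (the dedicated
continuous-circle oracle does that).

## Problem sizes in the shipped checks

The test and acceptance workloads use the grid above, 2·10⁵ oracle trials
per cell, 20 randomised planner configurations against a brute-force scan,
and a 10⁴-read closed-loop simulation on four 20 kb genomes — sizes at which
every binomial/multinomial 4σ acceptance band is a few per mille to a few
per cent wide, tight enough to catch real defects. The closed-loop fixture
profile places its error probabilities exactly on integer phred scores so
that quality quantisation is lossless and any recovery discrepancy reflects
a defect rather than rounding.
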