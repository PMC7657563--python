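# Methods

## Assay model and scope

All strategies assume a *noiseless* binary pooled assay: a pool tests
positive iff it contains at least one positive sample, regardless of pool
size. No false positives/negatives, dilution, Ct or limit-of-detection
modelling is included — the maximum pool size is reported precisely so a
user can judge detection-limit risk against their own assay validation.
Outcomes are exact counts, not estimates: given a design and a placement
of positives, tests, steps and pipettings are fully determined.

Ground truth is a length-N boolean vector; simulations place k positives
uniformly at random without replacement. Sample indices are 0-based and
abstract; 96-well plate semantics (column-major A1..H12 addressing) exist
only in the plate/protocol layer.

## Cost accounting

- **Tests (T)**: every pool tested counts once, including individual tests
  and second-round retests.
- **Steps (S)**: a step is a set of tests that can run simultaneously.
  Non-adaptive designs use 1 step (2 when an ambiguous decode forces a
  retest round). Multi-stage designs use one step per stage executed.
  Purely adaptive methods use one step per test, except that a batch of
  individual tests (the end-game of Generalized Binary Splitting) counts
  as one step because those tests are independent.
- **Pipettings (P)**: assembling a pool of m samples with a c-channel
  pipette takes ⌈m/c⌉ draws. The dispense into the destination well is not
  counted. Window-design (CRT) pools are staggered across the plate, so
  multichannel pipettes give no benefit there: P = N·w plus one draw per
  retest. Retests are always drawn single-channel. Within-plate adjacency
  is otherwise ignored; the plain ⌈m/c⌉ rule reproduces every checkable
  published pipetting count (e.g. 172/26/17 for S-Stage at N=96, k=k̂=1,
  and the validation plates below).
- **Controls**: `control_adjusted_tests` adds 2 controls per pool
  (`per_pool`, the convention for one-pool-at-a-time adaptive methods —
  tripling T) or 2 per step (`per_stage`, for batched designs).

## Strategy constructions

### CRT window pooling ("DNA Sudoku")

Windows must exceed √N and be pairwise co-prime, so any two samples share
at most one pool (their index difference would otherwise be a multiple of
two windows' lcm > N). Weight w = k̂ + 1. Decoding marks as candidates the
samples all of whose w pools are positive; with k ≤ w−1 true positives the
candidates are exactly the positives. The run is ambiguous iff there are
more than w−1 candidates (observably equivalent to k > w−1), in which case
all candidates are retested individually in a second step.

Window selection: the three preset sizes ship the published, validated
window sets (96: 10,11,13,17,19,23; 384: 20,21,23,29,31,37,41,43,47,53;
1536: 40,41,...,113). For other sizes, and beyond the published weights,
windows are chosen by a greedy upward scan from the smallest integer
exceeding √N, accepting each candidate co-prime to all already selected.
The greedy rule reproduces the 384 and 1536 sets exactly and the 96 set
through w = 5; at w = 6 it would accept 21 (= 3·7, co-prime to all five
predecessors) where the published set uses 23. No single deterministic
scan can produce all three published lists — 49 and 51 occupy the same
"composite squeezed between primes" position for 1536 that 21 does for 96,
and the three N share the same prime structure — so the published sets are
kept as design constants and the greedy scan is the documented general
rule. Past the published weights the extension is greedy (admitting e.g.
27 and 49 for N=96), which is stated here because alternative extensions
exist and none is canonical.

### 2D grid pooling

N samples fill M = ⌈N/D²⌉ square D×D grids sequentially, row-major; only
the last grid may be partial. Every non-empty row and column is pooled (an
empty line is not tested, and a partial line pools only its occupied
cells — this is what makes the 8-channel pipetting count 39 for one 10×10
grid holding 96 samples). Per grid, candidates are occupied cells at
intersections of positive rows and positive columns; a grid is ambiguous
iff it has more than one positive row *and* more than one positive column.
Candidates of ambiguous grids are retested individually in one shared
second step. The per-run ambiguity flag used in summaries means "at least
one grid ambiguous".

### S-Stage and Modified 3-Stage

Design formulas: S = ⌈ln(N/k̂)⌉ (floored at 1; capped at 3 for the
modified scheme) and nᵢ = ⌈(N/k̂)^((S−i)/S)⌉ with n_S = 1. Integer policy
throughout: ceiling for nᵢ, floor for the group count g = max(1, ⌊m/nᵢ⌋),
then an even partition of the m samples into g contiguous groups whose
sizes differ by at most one (larger groups first). This triple of choices
jointly reproduces the published worked examples (6 groups of 16; 5 groups
of 6 or 7; 4 groups of 3 or 4), test counts (13 and 14 at N=96, k=k̂=1),
maximum pool sizes (48/192/768 and 24/55/140 at k̂=1) and pipetting counts
(172 and 126); a last-pool-remainder split provably does not.

The two schemes differ only in re-pooling: S-Stage collects *all*
survivors of positive pools and redivides them collectively (preserving
index order); the Modified 3-Stage scheme subdivides each positive pool
independently, which keeps each pool's samples contiguous on the plate.
If every pool at some stage is negative, later stages are skipped and S
reflects stages actually executed (reachable only when k = 0 or the
estimate is badly off). The degenerate S = 1 design (k̂ ≥ N/e) tests all
samples individually in one step.

### Binary splitting

*Halving*: pool every unresolved sample; on a positive, binary-descend by
testing the first ⌈m/2⌉ indices of the active group. A positive tested
half narrows into it and returns the untested half to the pot; a negative
tested half clears it and transfers the search to the untested half, which
then contains a positive by elimination (asserted internally). After each
isolation all unclassified samples (sorted by index) are re-pooled. One
test per step, so T = S; max pool size is always N. The "first half,
⌈m/2⌉" convention is fixed for reproducibility; the published description
requires only "roughly equal" halves, so stochastic means can differ by a
small amount under other conventions.

*Generalized Binary Splitting*: initial group 2^α with
α = ⌊log₂((N′−k̂′+1)/k̂′)⌋ (clamped ≥ 0), recomputed from the current
unresolved count N′ and remaining estimate k̂′ after every isolation
(both symbols in the α formula are read as the current estimate). A
negative group is discarded whole; a positive group is binary-descended as
in halving, the isolated positive decrements k̂′. When N′ ≤ 2k̂′−2 the
remainder is tested individually as one parallel step; when k̂′ = 0 a
plain halving sweep over the unresolved samples guarantees completeness
(positives beyond the estimate are still found; k̂ plays no role inside
the sweep, and its first test is negative whenever the estimate was
exact). A size-1 pooled test classifies its sample directly.

Note on "maximum pool size" for this method: because α is recomputed, the
realized maximum pool in a run with many positives can exceed the initial
2^α (the design-time quantity); comparison tables report the design
quantity via `gbs_alpha`, while `ScreenOutcome.max_pool_size` is the
honest run maximum.

## Simulation driver

Default study conditions follow the benchmark design: sample sizes 96,
384 and 1536 (whole 96-well plates), k from 1 to 20, 100 replicates per
cell, positives placed uniformly at random. Replicate r of cell (N, k)
derives its placement seed from the root seed via `SeedSequence([root, N,
k, r])`, so runs are bit-reproducible and — because the derivation ignores
k̂ and strategy — misestimated and baseline cells share placements (common
random numbers). This makes the robustness deltas exact design effects;
per-cell resampling is available with `common_random=False`. Every
replicate hard-asserts that the decoded positive set equals the truth.

Summaries report mean, sample SD (ddof = 1), min and max per metric plus
the fraction of replicates with any ambiguous decode. `min_max_normalize`
rescales each feature column to [0, 1] across strategies (best = 0,
constant features map to 0) for radar-style comparisons.

## Plate protocols

Wells are addressed column-major (A1=0, B1=1, ..., H1=7, A2=8, ...), so the
Modified 3-Stage stage-1 pools for k̂ = 2 are exactly the six column pairs
(16 wells, two 8-channel draws) and stage-2 quarters are half-columns of
4 wells. Protocol sessions are pure functions of the observed pool
results: the CLI replays the full result history each call, so identical
inputs always give identical instructions. The validation replay drives
one session per plate from a spike map and cross-checks its test and
pipetting counts against the index-level simulator.

Known discrepancy: for the validation experiment's plate 1 (three
positives, none sharing pools) the ⌈m/8⌉ accounting gives 36 pipettings
while the experiment's records report 48; the same accounting reproduces
the other seven plates exactly, so the replay reports the formula value.
Test counts are unaffected (30 for that plate; 120 across all eight).

## What the simulations do and do not show

The generator emulates exactly the benchmark's idealised conditions:
uniform random positives, a perfectly accurate assay, no pool-size limit,
no sample-volume exhaustion. Real screens face assay error (a single false
negative can clear a large pool), detection limits that cap usable pool
sizes, clustered rather than uniform positives, and mid-campaign changes
in carriage rate. Passing tests therefore validate the combinatorial
designs and their cost accounting, not field performance of any assay.
k̂ is fixed for a whole run; re-estimating it mid-procedure is out of
scope.

## Numerical choices

- Stage-size formula values are rounded to the nearest integer first when
  within 1e-9 (guarding float noise like 8.000000000000002) and otherwise
  ceiled.
- `place_positives` uses numpy's PCG64 via `default_rng(seed)`.
- Derived seeds are reduced mod 2³¹.
- `even_partition` puts larger groups first; stage pools are contiguous
  runs of the surviving-sample ordering.
- A k̂ < 1 passed to Generalized Binary Splitting is coerced to 1 with a
  warning (the design is undefined there); the staged designs reject it.
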