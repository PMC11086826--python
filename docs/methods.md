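# Methods

## Null models

Given a binary biadjacency matrix **B** (nA agents × nB artifacts), both
null models draw random matrices **B\*** with independent Bernoulli cells.
The cell probabilities are the maximum-entropy solution subject to the
expected-degree constraints `E[Σ_k B*_ik] = deg(i)` and
`E[Σ_i B*_ik] = deg(k)` — the bipartite configuration model, in which free
cells have `q_ik = x_i y_k / (1 + x_i y_k)` for positive row and column
multipliers. Under edge constraints (SDSM-EC), REQUIRED cells are fixed at
`q = 1`, PROHIBITED cells at `q = 0`, and the free cells are fitted to the
adjusted margins (observed degree minus the number of required cells in
that row or column). With an all-FREE mask the constrained and
unconstrained fits are the same code path, so SDSM is exactly the
zero-constraint special case of SDSM-EC.

Fitting proceeds in three stages:

1. **Feasibility and degeneracy reduction.** Margins outside
   `[0, #free cells]` raise an error (they cannot occur for a mask that is
   consistent with the observed matrix). Rows/columns whose adjusted margin
   is 0 or equals their free-cell count are resolved exactly (all free
   cells 0 or 1), margins updated, and the reduction repeated to a fixed
   point; this also handles complete and empty matrices without iteration.
2. **Multiplicative fixed point.** `x_i ← r_i / Σ_k y_k/(1 + x_i y_k)` and
   symmetrically for `y`, initialized from the free-cell density, with
   geometric damping (`x ← √(x_old·x_new)`) engaged if the residual ever
   increases. Up to 500 iterations.
3. **Newton polishing.** If the fixed point has not reached tolerance
   (near-saturated margins make it crawl), a damped Newton iteration on the
   log-multipliers with a backtracking line search finishes the job. The
   margin system is invariant under `x → tx, y → y/t`, so the Jacobian
   carries a tiny ridge for the gauge null-direction.

Convergence is declared when the maximum absolute degree residual is below
`tol` (default 1e−8, checked against the original margins including fixed
cells); non-convergence within `max_iter` (default 10,000) raises, and
infeasibility is never silently clipped. The fit is deterministic for fixed
input.

## Significance test

Under either null, the weight of projection edge (i, j) is a sum of
independent Bernoulli trials with success probabilities `q_ik · q_jk`
(required cells contribute certain successes, prohibited cells certain
failures). P-values use the inclusive upper tail `Pr(X ≥ w)` — the
conservative convention for discrete statistics — and retention is strict
(`p < α`), so a weight of 0 (p = 1) can never enter the backbone and
raising α never removes an edge. Two evaluators:

* **exact** — dynamic-programming convolution of the Bernoulli factors
  (deterministic cells folded in without widening the support); used by
  `method="auto"` while nB ≤ 512;
* **rna** — continuity-corrected normal with a first-order skewness
  correction, clamped to [0, 1], falling back to the exact tail for
  zero-variance cases; measured against the exact tail it is within
  ~1e−3 at nB = 50 and within ~5e−5 at nB = 1829.

No multiple-testing correction is applied by default (backbones are
conventionally thresholded at a fixed α); Holm and Benjamini–Hochberg
adjustments are available behind a flag.

## Comparison statistics

Backbones on the same agent set are compared as binary classifications of
the nA(nA−1)/2 unordered pairs: confusion counts (the reference backbone is
the positive-truth side), phi (Pearson correlation of the indicator
vectors, computed from the confusion counts in closed form), Cohen's kappa,
Jaccard = TP/(TP+FP+FN), and FDR = FP/(FP+TP). When either indicator vector
is constant, phi and kappa are undefined and reported as NaN with a
warning; two empty backbones get Jaccard 1 (perfect agreement of empty
sets) so that replicate averages in the sweep remain well-defined, and an
FDR with no positives is NaN. Replicates with undefined indices are
dropped from sweep means and counted per cell.

## Synthetic generators

**Sweep instances.** Each replicate draws an iid Bernoulli(density)
biadjacency matrix (default 20 × 100 at density 0.5), then marks a uniform
random X% of present cells REQUIRED and Y% of absent cells PROHIBITED
(rounded half-up, sampled without replacement), so the mask is consistent
with the graph by construction. Replicate r of grid cell (X, Y) uses an RNG
seeded from the tuple (seed, X, Y, r); all pipelines are bit-reproducible
for a fixed seed.

A consequence worth stating plainly: because the generated data are
*exactly* the kind of network the degree-matched null describes, both SDSM
and SDSM-EC are correctly specified for them, and at α = 0.05 the extracted
backbones are empty in most replicates (the test is additionally
conservative on small agent modes, where conditioning on realized degrees
shifts the null mean of a pair weight upward — about +1.2 shared artifacts
at 20 × 100, density 0.5). The phi correlation between the two backbones is
then undefined in most replicates and the sweep's correlation surface rests
on the minority of replicates with non-degenerate backbones; the Jaccard
surface (with the empty–empty = 1 convention) is defined everywhere and
carries the same qualitative message: agreement between the
constraint-ignoring and constraint-aware backbones decays as constraint
prevalence grows. Passing sweep tests therefore demonstrate the divergence
mechanism, not detection power on structured data — for that, see the
play-group generator below, which plants a ground truth.

**Play-group worlds.** The scan-sampling generator emulates observational
play-group data: children split across two age-segregated classrooms
(default 26/27 of 53) with AM/PM/FULL attendance schedules (default
probabilities 0.3/0.2/0.5); 1829 groups by default, each observed in one
classroom (chosen proportionally to classroom size) and one session
(AM/PM equiprobable), around a uniformly chosen schedule-eligible focal
child who is necessarily a member; additional members (group sizes uniform
2–6, truncated to the eligible pool) are sampled with an odds multiplier
(`assortativity`, default 1) per already-chosen friend in a planted
within-classroom Bernoulli friendship network (default density 0.15).
The generator does not model temporal ordering of scans, repeated-group
autocorrelation, or behavioral realism; it exists so the full empirical
pipeline (constraint masks from attribute tables, coercion, accounting,
backbones, comparisons) can run end to end on data with a known truth.

The three constraint families are derived from attribute tables exactly as
in the observational design: focal membership REQUIRED; cross-classroom
cells PROHIBITED (age); AM-child/PM-group and PM-child/AM-group cells
PROHIBITED (time). REQUIRED takes precedence in mask unions; a focal child
prohibited for its own group is an attribute inconsistency and raises.

## Coercion of impossible observations

A PROHIBITED cell observed present (e.g. a recorded membership the time
rule declares impossible) is, under `mode="coerce"`, set to 0 with each
coercion reported; the empirical pipeline runs in this mode, so a present
edge reclassified by the time rule moves into the prohibited column of the
edge accounting and the four accounting columns always sum to nA·nB.
A REQUIRED cell observed absent is never repaired silently and always
raises. Strict mode is the default everywhere else.

## Empirical-style comparison

For each of the eight subsets of {focal, age, time}: build the mask, coerce,
account edges, fit SDSM-EC, and extract the backbone at α = 0.13 (the
conventional level for these play-group data; the synthetic sweep uses
0.05). Every backbone is scored against the maximally-constrained one. The
accuracy-vs-constraints statistic is the Pearson correlation between
phi-vs-reference and the number of constrained cells over the seven
non-reference conditions (the reference row has no self-comparison value in
the study's table layout; including it as an eighth perfect point is a
defensible alternative we do not take).

## Problem sizes and numerical choices

The shipped tests and the acceptance script use: enumeration oracles up to
2¹⁵ outcomes for the Poisson-binomial; degree-matching checks up to the
full 53 × 1829 scale; 1,000 Monte-Carlo replicates on a 10 × 50 fixture for
null calibration of the retention rate; 100 replicates per sweep cell at
20 × 100; and 16-children × 600-group worlds over 20 seeds for the
planted-truth recovery property (with assortativity 8 the constraint-aware
backbone attains mean Jaccard ≈ 0.4–0.5 against the planted truth versus
≈ 0.1–0.2 for the constraint-ignoring one: ignoring constraints
underestimates within-classroom co-membership rates and floods the
backbone with false positives). Ties and boundaries are fixed by the
inclusive-tail/strict-threshold conventions above; degenerate inputs
(empty or complete rows/columns, all-zero probability vectors) are resolved
exactly before any iteration.

## Known limitations

* Exact-degree (fixed degree sequence) nulls and swap-based randomization
  are out of scope; the null family here is Bernoulli cells matched in
  expectation.
* The refined-normal tail is an approximation; `method="exact"` is always
  available and `auto` switches on the artifact-mode size, not on an error
  estimate.
* On iid random data the backbone test is conservative (see above);
  reported sweep correlations are means over replicates where the statistic
  is defined, with the undefined count reported alongside.
* The play-group generator is a structural emulation, not a behavioral
  model; conclusions from it transfer to real data only insofar as the
  constraint structure (not the social dynamics) drives the result.
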