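# Methods

`rigc` implements a complete measurement-and-analysis chain for behavioral
complexity: estimating the algorithmic complexity of the short pseudo-random
sequences people produce in random item generation (RIG) tasks, and
characterizing how that complexity changes across the lifespan. This note
documents the models, the numerical choices, and what the synthetic data can
and cannot show.

## Complexity estimation

### Machine spaces and the coding theorem

Kolmogorov–Chaitin complexity K(s) — the length of the shortest program that
prints s and halts — is uncomputable, but for short strings it can be
approximated through algorithmic probability: simple strings are produced by
many small programs. We enumerate (or sample) the space of small Turing
machines with n states and k tape symbols (blank = 0), run each machine from
an all-blank tape, and record the output of every run that halts within a
step cap. The Coding Theorem Method (CTM) estimate is

    K(s) = −log2( count(s) / total_halting )   [bits].

Conventions that make tables reproducible bit-exactly:

* A transition entry is either (write, move, next state) or (write, halt);
  1-D machines move left/right (2·k·n + k entries per table cell), 2-D
  "turmites" move in four directions (4·k·n + k). The (2,2) 1-D space
  therefore has exactly 10⁴ machines and the (2,2) 2-D space 18⁴ = 104 976.
* The output is the tape segment spanned by every cell the head visited
  (minimal bounding rectangle in 2-D); a machine that halts on its first
  step outputs the single origin cell. The halting transition counts as a
  step.
* Runs that do not halt within the step cap are excluded from both numerator
  and denominator. Step caps default to the known busy-beaver bounds
  (6 for (2,2), 21 for (3,2), 107 for (4,2)) and 500 elsewhere; a cap below
  a known bound triggers a warning.
* Outputs are canonicalized by symbol order (first distinct symbol → 0,
  next → 1, …). This removes the arbitrary identity of symbols, so K is
  invariant under any permutation of the response alphabet.
* Strings absent from a table fall back to (max covered K + 1 bit), flagged
  in every score that uses it. This preserves the frequency ordering and
  keeps all scores defined where coverage is partial.

Two independent simulator implementations exist: a naive dict-tape reference
and a compiled (numba) batch kernel. The test suite requires them to agree
exactly on the full (2,2,1-D) distribution.

### Built-in desk-scale tables

Published CTM tables rest on spaces of up to ~2.7×10¹³ machines; this package
deliberately works at desk scale and rebuilds its tables deterministically in
seconds: exhaustive (2,2) in 1-D and 2-D, and 200 000-machine uniform samples
of the (2,5), (2,6) and (2,9) spaces (fixed internal seed, so every process
reconstructs identical tables). Absolute K values therefore differ from the
published tables by design; what the analysis relies on — and what the tests
check — is the *ordering* (frequent/regular strings score low) and the exact
normalization identity below.

### Block decomposition and per-task scoring

No desk-scale space covers full-length task strings (a (2,2) machine halting
within 6 steps spans at most 7 cells), so task responses are scored with the
Block Decomposition Method (BDM): partition the response into non-overlapping
blocks (remainders keep their natural size) and sum, over distinct blocks,
K(block) + log2(multiplicity). Block length 3 is used for all sequence tasks:
it is the longest length at which the exhaustive (2,2) table covers every
canonical binary class, and the sampled multi-symbol tables cover all five
canonical 3-symbol classes. The 3×3 grid is scored with 1×3 row blocks
against the 2-D table (native whole-grid lookup is impossible at this scale:
no (2,2) turmite halts with a 3×3 bounding box). A string the table covers in
full is looked up directly; block counting is over raw (uncanonicalized)
blocks, which relabeling permutes bijectively, so scores remain
permutation-invariant.

### Normalization

Raw K is standardized against the full response space of the task: with μ and
σ the mean and SD of K over all alphabet^length strings,  z = (K − μ)/σ.
Zero is thus the mean complexity of all possible strings, and z is comparable
across tasks. The moments are computed exactly without enumerating the space:
K is constant on symbol-permutation classes, so we iterate canonical classes
(restricted growth strings) and weight a class with d distinct symbols by
k!/(k−d)!. For the 9-circle task this reduces 9¹⁰ ≈ 3.5×10⁹ strings to
~116 000 classes (seconds). The identity mean(z) = 0, SD(z) = 1 over the full
space holds to 10⁻⁹ for every task and is enforced by the acceptance tests.

First-order Shannon entropy of the empirical symbol distribution is provided
as a comparator; the strictly alternating string attains maximal entropy yet
scores below the median complexity, which is exactly the failure mode that
motivates an algorithmic measure.

## The five tasks

coin: 12 binary tosses · card: 10 guesses among 5 Zener cards · die: 10 rolls
of faces 1–6 · circles: 10 pointings at 9 circles · grid: a 3×3 binary grid
(scored on its final configuration; the click count is retained in the data
model but does not enter the score). The card task is scored like the
explicit randomization tasks. Responses are stored as 0-based digit strings.

## Synthetic cohort generator

The generator emulates the statistical structure a lifespan RIG study
assumes, so the full chain can be exercised without any participant data.

**Demographics.** Ages are integer years from a truncated normal
(mean 37.72, SD 13.38) on [4, 91]; sex ~2:1 male:female; education levels
1–7 follow the study-like marginal, capped by age (children are not
postgraduates); a field of education (humanities/science/other) is assigned
only above age 15; paranormal belief is uniform on the 1–6 Likert scale.

**Ability curve.** Each participant carries a latent randomization ability
in [0, 1]: a monotone-segment PCHIP through five knots — (4, 0.43),
(16, 0.79), (25, 0.85), (60, 0.50), (91, low) — plus Gaussian noise
(SD 0.08), clipped to [0, 1]. The curve rises steeply through childhood,
decelerates into a rounded summit at 25 (the adolescent knot gives the peak
locally symmetric curvature, without which a df = 7 smoother displaces the
argmax of such an asymmetric kink by several years), declines slowly to 60
(0.010/yr) and about twice as fast afterwards (0.022/yr).

**Response model.** Responses are sampled sequentially; the next-symbol
distribution is uniform, reweighted by the classic randomization heuristics:
immediate repetition down-weighted (strength 0.95), the binary alternative
boosted (0.6), unused symbols favored until all have appeared — the cycling
bias (0.85) — and, on the grid only, the previous row repeated verbatim with
some probability (pattern perseveration, 0.55). Heuristic strength scales
with √(1 − ability): residue fades slowly at first (even competent
randomizers keep mild habits) and vanishes exactly at ability 1, where
responding is i.i.d. uniform. Setting any strength to 1 at ability 0 makes
the corresponding rule deterministic (e.g. full cycling ⇒ the first k
symbols are a permutation of the alphabet).

**Covariate effects.** Completion times are lognormal (shape 0.35) around a
U-shaped age median (fastest near 25), with a multiplicative male factor of
0.93; per-task medians are 15–25 s. Paranormal belief lowers grid-task
ability by 0.01 per point. The grid click count is the number of black cells
plus a geometric number of toggle pairs — a placeholder mechanism, not
calibrated against any reported click statistics.

All parameters above were fixed once, by inspecting whether simulated
trajectories reproduce the qualitative lifespan pattern the analysis is
designed to detect (peak near 25, slow then accelerating decline, male CT
advantage, small negative belief→grid effect). The generator is a statistical
emulation, not a cognitive model: it contains no working-memory or attention
dynamics, no practice or drop-out effects, and its age effect on mean
complexity (~6% of variance) is stronger than in real data (~2% is reported
for comparable designs) — a deliberate trade-off that keeps the peak
recoverable from a single desk-scale cohort. Passing tests therefore show
that the *pipeline* recovers injected structure at realistic n, not that the
bias model is cognitively accurate.

## Trajectory analysis

**Smoothing splines.** The lifespan trajectory of a score is a cubic
smoothing spline of the score on age at df = 7 equivalent degrees of
freedom. Following the classic smooth.spline convention, observations are
collapsed to unique ages with counts as weights; the penalty λ is calibrated
by bisection so that the trace of the smoother matrix equals the requested
df (the trace is evaluated by smoothing unit vectors). As λ → ∞ the
natural-spline fit tends to the straight line (df → 2); that limit is
computed exactly as a weighted least-squares line rather than with an
enormous, ill-conditioned penalty. The peak age is the argmax of the fit on
a 0.5-year grid over the observed age range; a flat fit (range < 10⁻⁹)
reports "no unique peak". 95% confidence regions use a case-resampling
percentile bootstrap (default 500 replicates) at the λ calibrated on the
full sample. The speed–accuracy path is the parametric curve
(fitted CT(age), fitted z(age)) on the shared grid.

**General linear models.** Modulating factors are assessed with OLS models
per dependent variable: centered age and age² (a quadratic-only switch
exists; an inverse-U needs the quadratic, and centering tames collinearity),
categorical sex and field, ordinal-numeric education, numeric belief.
Analyses including field or belief are restricted to participants above 15.
Reported per term: coefficient, Type II F-test p-value, partial
η² = SS_term/(SS_term + SS_residual), plus a Holm-adjusted column
(primary p-values are reported unadjusted, per common practice in this
literature). Rank-deficient designs raise an error naming the aliased
columns; models require ≥ 10 complete cases per term.

**Reliability and correlations.** Internal consistency across tasks uses
Cronbach's alpha, k/(k−1)·(1 − Σ item variances / variance of the sum), on
complete cases (the source literature labels this "Cohen's α"; the formula
is Cronbach's). Age-windowed Pearson correlations (e.g. CT vs complexity in
the 25–60 range) use complete cases in the window and error on degenerate
variance.

## Problem sizes and determinism

Default analysis sizes: cohorts of n = 3429; exhaustive spaces of 10⁴ (1-D)
and ~10⁵ (2-D) machines; 200 000-machine samples per large-alphabet space;
moment computation over ≤ 116 000 canonical classes per task. Every
stochastic stage takes an explicit seed; a run's config plus seed determines
its outputs byte-for-byte (seeds for the cohort's demographic, response and
timing streams are spawned from one root SeedSequence).

## Known limitations

* Absolute K values depend on the desk-scale machine spaces and are not
  comparable to published full-scale tables; only orderings and normalized
  scores are meaningful here.
* Coverage of long strings is indirect (through BDM); the per-block
  granularity bounds how finely two responses can be distinguished.
* The grid score, built from 1×3 row blocks, is blind to purely columnar or
  diagonal structure.
* The generator's biases are qualitative stand-ins; effect magnitudes are
  calibrated for detectability, not estimated from data.
* Cross-sectional only: the synthetic cohorts contain no longitudinal or
  cohort effects, and the trajectory machinery would conflate them if they
  existed.
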