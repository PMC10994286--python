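# Methods

This note documents the models, numerical choices, and simulation
conditions implemented in `sorsvf`, and what the synthetic-data results
do and do not establish about real perimetric data.

## Grid and conventions

The 24-2 grid is constructed as every (x, y) with |x|, |y| ∈ {3, 9, 15,
21} degrees and |x| + |y| ≤ 30 (52 points), plus two nasal-extension
points at (−27, ±3).  Coordinates are right-eye (OD) convention,
temporal = +x, superior = +y; left-eye fields are mirrored (x → −x) on
load.  The physiologic blind spot maps to the two locations at (+15, ±3).
Location order is fixed (descending y, then ascending x) but internal:
all user-facing output goes through grid coordinates.

Blind-spot handling: all 54 locations participate in reconstruction
models and in point-wise RMSE — the first principal component of
glaucomatous data explicitly captures the blind spot, so excluding it
would misrepresent the models.  Mean deviation (MD), used only for
severity stratification, averages the 52 non-blind-spot locations with
equal weights against the training-derived normative hill; no age
correction is applied.  When a dataset file carries its own MD column it
is preferred over the recomputed value.

Thresholds live in [0, 40] dB with 1-dB stimulus resolution, the dynamic
range of a standard projection perimeter.  Model fitting uses raw
(unclipped) values; predictions are clipped to the instrument range only
at reconstruction time, keeping the fits linear and the outputs physical.

## Reconstruction models

All four reconstructors are affine maps from the measured subset
s ∈ ℝ^S to a 54-vector estimate.

* **mean** — the per-location training mean (hill of vision); ignores s.
* **LR** — ordinary least squares, x̂ = D s + β, solved by minimum-norm
  least squares (pseudoinverse).  No regularization: rank deficiency
  (training sample smaller than subset size) yields the minimum-norm
  solution rather than an error.
* **TTPCR** — a PCA basis (mean μ, top-n eigenvectors W of the sample
  covariance B Bᵀ/(N−1)) is fitted once on the training matrix and frozen
  for every subset; the regression D, β is then fitted from s to the
  embeddings Wᵀ(x − μ), and predictions are expanded as W(Ds + β) + μ.
  Algebraically the prediction equals the orthogonal projection of the LR
  prediction onto the principal subspace, which is the mechanism of its
  robustness: directions the training data cannot support are removed.
* **PLS** — a rank-n affine map x̂ = W D s + β trained iteratively.  The
  backend is scikit-learn's PLS2/NIPALS with both-block deflation,
  convergence tolerance 1e−6 on the weight vectors and at most 500
  iterations per component; non-convergence is logged and the best
  iterate kept.  The effective rank is capped at min(n, S, N−1).

Numerical determinism: the PCA eigendecomposition is computed by SVD of
the centered matrix, and each component's largest-magnitude entry is made
positive, so repeated fits are bit-identical across runs.  When n exceeds
the rank of the training matrix the basis is padded with a deterministic
orthonormal complement; this preserves the exact n = 54 equivalence of
TTPCR with LR even for small training samples.  Note that in the
*rank-deficient* regime (N ≤ S) the minimum-norm LR and full-basis TTPCR
agree on training fields but may legitimately differ on new inputs — the
limit identity is a full-rank statement, and the tests exercise it there.

The default embedding dimension is n = 8, the smallest dimension at which
reconstruction accuracy saturates on both small and large training sets;
it is configurable in 1..54.

## SORS training

Greedy forward selection: at step k, every remaining candidate location
is tentatively appended, a reconstructor is refitted on the augmented
subset, and the candidate with the lowest training mean-squared error
over the whole field (all 54 targets, all N training columns, in dB²) is
kept.  Ties break to the lowest location index.  The result is an order
plus one fitted model per prefix length.  Greedy selection does not
guarantee the globally optimal ordering; exhaustive search over
permutations is infeasible and the greedy order is the defining
procedure.  Candidate refits use the naive least-squares semantics
directly (no factorization reuse): a full 54-step training pass at
N = 250 takes well under a minute on one CPU, so there is nothing to
optimize.

The mean-baseline "plan" orders locations by descending training
variance — with a measurement-blind reconstructor, testing the most
variable locations first is what greedy error reduction degenerates to —
and its reconstruction always returns the hill of vision.

At test time the final estimate keeps the *measured* values at tested
locations and model output elsewhere (substitution).  Pure model output
is also computed and reported alongside (`rmse_raw`), since substitution
at tested locations can only reduce the error there and conventions
differ between studies.

## Threshold procedures

**Responder model.**  The probability of "seen" for a stimulus at s dB
given true threshold t is fp + (1 − fp − fn) · clip(0.5 + (t − s)/(2w),
0, 1): a linear ramp of half-width w from the false-negative ceiling to
the false-positive floor.  Default w = 2 dB, a piecewise-linear
approximation of a cumulative Gaussian with SD ≈ 1.6 dB; w = 0 gives a
step function (used for determinized tests), and a threshold-dependent
Henson-type half-width is available (`henson_halfwidth`).  The default
reliable responder has fp = fn = 3%; 15%/3% and 15%/15% configurations
reproduce the less-reliable conditions.

**ZEST.**  The estimator maintains a PMF over the integer domain
0..40 dB.  The prior is the pooled histogram of all training thresholds
(all locations, all fields) plus an additive floor of 1e−3 per bin after
normalization (~4% total uniform mass) — the floor keeps thresholds
outside the training support reachable.  Pooling rather than per-location
priors is the default; per-location priors are a configuration choice.
Stimuli are placed at the posterior mean rounded to the 1-dB grid
(standard ZEST placement); the likelihood uses the *estimator's* assumed
fp = fn = 3% and w = 2 regardless of the simulated responder's actual
rates — deliberate, since a perimeter does not know its patient — and the
procedure stops when the posterior SD drops below 2.0 dB (strict
inequality) or after a safety cap of 30 presentations per location.  The
estimate is the unrounded posterior mean.  Seeded locations reuse the
empirical prior translated by an integer shift so its mean matches the
reconstruction's prediction, with mass pushed past the domain edge
accumulating in the edge bin.

**4-2 staircase.**  Stimuli move 4 dB per step (dimmer after "seen",
brighter after "not seen") until the first response reversal, then 2 dB
until the second; the estimate is the last seen level (0 dB if nothing
was seen).  At the 0/40 dB limits a repeated pinned presentation counts
as a reversal, bounding the procedure.  Start direction, reversal count
and the last-seen rule follow the classic full-threshold convention; the
literature varies on these details, so they are isolated in one function.

## Simulation harness

Locations are opened in plan order in batches of four (configurable);
within a batch, locations run to completion sequentially — with
conditionally independent locations this is distribution-identical to
interleaving, which matters only for human subjects.  After each batch
the whole-field estimate is refreshed and the RMSE trajectory extended;
the test stops after `stop_after` locations (36 and 54 are the
interesting settings) and untested locations keep the final
reconstruction value.  The quadrant baseline tests the four quadrant
centers first and grows outward breadth-first within each quadrant, each
new location seeded with the mean deviation-from-normative of its
already-determined within-quadrant neighbours; the independent baseline
uses the unshifted pooled prior everywhere and the hill of vision for
untested locations.

Cross-validation splits by *eye*, so repeated visits never straddle a
train/test boundary: the small scheme trains on one of five folds (20% of
eyes) and tests on the rest; the large scheme trains on nine of ten folds
(90%).  Per-field RNG streams are derived from (master seed, fold,
strategy index, field index), so adding a strategy or field does not
perturb existing draws, and every result is bit-reproducible from the
(dataset, configuration, seed) triple.

The embedding-dimension sweep evaluates reconstruction RMSE at a
checkpoint (default 36 locations) using the *true* thresholds as the
measured values, isolating reconstruction error from threshold noise;
a ZEST-based sweep is a matter of swapping the harness call.

## Synthetic generator

Each simulated eye superposes: a normal hill of vision
33 − 0.07·(x² + y²)^0.8 dB with a constant −1 dB superior offset and
blind-spot locations forced to 3 dB; an eye-level height offset
N(0, 1.5 dB); and a severity-scaled non-negative mixture of six defect
archetypes — global depression, superior/inferior arcuate (a Gaussian
band around 15° eccentricity confined to one hemifield),
superior/inferior nasal step (deepening toward the nasal periphery, one
hemifield), and a temporal wedge.  Focal weights are Dirichlet(0.35)
(sparse: one or two patterns dominate), the global share uniform in
0.2–0.6, and the mixture is scaled so the mean depression hits a target
drawn per severity class (normal 0–1, mild 1–6, moderate 6–12, severe
12–22 dB).  Visits of one eye share all eye-level parameters and differ
by N(0, 1.5 dB) measurement noise per location; eye-level and visit-level
draws use disjoint seed streams.  Class prevalences default to
0.35/0.30/0.20/0.15; the stored severity label is re-derived from the
realized mean deviation, so labels always agree with the MD stratifier.

The defaults reproduce the statistical structure the method relies on:
~95% of variance in the first 8 principal components, adjacent
same-hemifield correlations above 0.8 (often >0.9), a bimodal pooled
threshold histogram, and — at the default 278-eye scale — greedy SORS
orders whose first four locations span all four quadrants.

What the generator does *not* emulate: progression across visits,
realistic floor-effect censoring beyond clipping at 0 dB, fixation-loss
artifacts, and any particular clinic's prevalence mix.  Consequently,
passing tests demonstrate that the algorithms behave as specified under
the assumed low-rank spatial structure; they do not certify performance
numbers on any real population — for that, load a real dataset through
`load_dataset` and rerun the same harness.

## Problem sizes used in the shipped tests and acceptance script

The test suite trains on datasets of 40–1390 fields and simulates tens of
full field tests; the acceptance script uses a 200-field training sample
and 100 test fields.  These sizes give stable means (the per-field
presentation count varies by ~3 trials across seeds at n = 100) while
keeping a full run in seconds on one CPU.

## Known limitations

* The greedy order is locally optimal only; no global guarantee.
* PLS uses both-block NIPALS deflation; other deflation conventions give
  slightly different (equally defensible) factors.
* The ZEST domain is integer dB; procedures with finer stimulus grids
  would need a wider domain PMF.
* Minimum-norm behavior in the rank-deficient regime is a choice, not a
  canonical answer; ridge-type regularization is deliberately absent
  because the ordinary-regression baseline is part of the design.
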