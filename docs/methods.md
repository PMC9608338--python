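# Methods

## Movement model

Cursor control is modeled with the Shannon formulation of Fitts' Law,
MT = a + b·ID with ID = log₂(D/W + 1), where D is the Euclidean distance
between sequential click points in pixels and W = 130 px is the key width
(actual width, not effective width: the task gives unlimited chances per
target, so the error rate of a completed selection is zero and W is the
appropriate normalizer). The extension at the core of the package is
*directional*: movement direction θ is discretized into 16 bins of 22.5°
(four cardinals, four intercardinals, eight half-winds) and (a, b) are
fitted independently per bin, yielding a piecewise-constant directional
movement model.

Angle convention: 0° is rightward and 90° is upward *as the user sees it*
(screen y grows downward and is flipped before `atan2`). Bin k covers the
half-open arc [22.5k − 11.25°, 22.5k + 11.25°), so each named direction
owns a symmetric arc; the upper edge belongs to the next bin, making the
bins an exact partition of [0°, 360°).

## Grid geometry

Keys are pointy-top hexagons in an odd-r offset honeycomb: odd rows shift
right by W/2 and rows are W·√3/2 apart, so all adjacent keys are exactly W
apart center-to-center and a k-key separation along a row is exactly k·W.
The hexagon orientation and row-offset parity are conventions of this
package (either choice yields the same distance structure); coordinates are
0-based with row 0 at top and the pixel origin at the top-left key center.

## Characterization task

The task queue seeds 25 targets at each of nine separation levels 0–8
(225 total), shuffled by the task seed. Levels are key separations: level k
asks the planner for a target whose center distance from the current key is
within ±0.5 W of k·W (the window widens in 0.25 W steps when the grid
cannot realize the nominal distance, e.g. level 8 from an interior key).
The nine levels are read as separations rather than integer bit values
because an 8-bit ID would require a distance of 255 key widths, which no
on-screen grid can realize; the straight-line ID of level k is log₂(k+1),
spanning 0 to ~3.17 bits. Among distance-feasible keys the planner prefers
the least-covered direction bin, breaking ties uniformly at random, which
empirically balances bins to ~12–13 trials each after the initial queue.

Level-0 targets re-select the current key (D = 0, ID = 0). They estimate
the user's shared reaction floor but carry no direction, so by default they
are *excluded* from the per-bin regressions (`SeedConfig.include_zero_in_bins`
turns inclusion on). Rationale: a zero-distance selection time reflects a
direction-free click cost; folding it into every bin's regression drags
each bin's intercept toward the across-bin mean and destroys the
per-direction intercepts the profile exists to capture.

After the queue, each bin is fitted by ordinary least squares of MT on ID
(closed-form normal equations; R² = 1 − SSres/SStot, residual SD with
n − 2 denominator). A bin passes when n ≥ 10, the IDs take at least two
distinct values, and R² > 0.25 (strict). Trials whose residual strictly
exceeds 3 residual SDs are outliers; an outlier is considered repeated
once a later trial lands in the same bin at the same level. Each pass the
task appends, per failing bin, three targets at separations 1, 4 and 8
(spreading ID support) plus one target per unrepeated outlier, stopping
when every bin passes or exactly at the 400-target cap. Residual SDs below
1e-12 are treated as exact fits so floating-point roundoff cannot flag
spurious outliers on noiseless data.

### What recovery the task can support

With 225 seeded targets, 25 are level-0, leaving ~12.5 directional trials
per bin. Because the minimum inter-key distance is W (and ~1.73 W for
vertical bins), the per-bin regression has no support below ID = 1 and the
intercept is an extrapolation: at noise σ = 0.1 s its standard error is
0.07–0.13 s depending on direction. Slopes are recovered much more tightly
(SE ≈ 0.04 s/bit). Consequently, per-bin intercept recovery to ±0.15 s
succeeds in roughly 80–85% of bins for users with strongly varying
directional intercepts, while slope recovery exceeds 97%. The adaptive
loop does not change this, since its trigger is correlation quality, not
parameter precision. Noiseless users are recovered exactly (to 1e-6).

## Synthetic users

`UserModel` holds ground-truth per-bin (a*, b*), movement-time noise SD,
a per-selection miss probability, and a 0.05-s movement-time floor that
prevents non-physical draws (configurable). A selection at angle θ draws
MT = max(floor, a*(bin θ) + b*(bin θ)·ID + ε), ε ~ N(0, σ²). Zero-distance
selections use the mean of a* across bins (a direction-free click cost).

Two miss semantics mirror the two tasks. In characterization, chances are
unlimited: each failed attempt (probability `miss_prob`, independent) costs
a fresh MT draw and the attempt count is geometric with mean 1/(1 − p).
In transcription, errors go uncorrected: a miss selects a uniformly random
key adjacent to the target and the walk continues from it. The first
character of a prompt is measured from the layout's centroid key (the
cursor's natural homing position; the true start is not observable in a
simulated session).

The generator emulates the movement-time structure, directionality, noise,
and click errors of a point-select user. It does not emulate trajectory
dynamics, visual search for unfamiliar layouts, learning or fatigue across
sessions, or within-session drift — so passing tests demonstrate the
correctness of characterization, optimization and metrics, not human-level
outcomes; absolute simulated rates (e.g. ITR) are higher than those of real
alternative-access users.

## Layout optimization

Flow is the 27×27 matrix of digraph counts over A–Z and space. Corpus text
is uppercased, whitespace runs collapse to one space, and out-of-alphabet
characters are dropped *and break adjacency* (the digraph straddling a
dropped character is not counted). Double letters count on the character
diagonal and pair with the same-key re-selection time — real cost on a
single-input keyboard. Counts are used raw: the argmin is scale-invariant,
and the solver normalizes flow internally so even the seeded search
trajectory is scale-invariant.

The distance matrix over M candidate positions is built in three steps per
ordered pair: selection angle → profile constants for that angle (invalid
bins fall back to the nearest valid bin by circular distance, averaging on
ties) → Fitts' Law at the pair's distance. The diagonal is the mean valid
intercept (re-selection). The default footprint of the M = 27 positions is
a hex spiral: grid keys sorted by distance from the central key (ties by
angle) — compact, deterministic, and configurable.

The assignment minimizing E(π) = Σ f[i,j]·d[π(i),π(j)] is found with
scipy's Fast Approximate QAP solver, run from the barycenter plus
`restarts − 1` random permutation-matrix initializations (permutation
matrices are the extreme points of the doubly-stochastic polytope; they
diversify the search far better than near-barycenter perturbations, raising
the exact-optimum rate on random 6×6 instances from ~74% to ~98% at 32
restarts). Solver hyperparameters: maxiter 100, tolerance 1e-8, seeded.
With M > N the flow is zero-padded and dummy placements discarded;
`brute_force_qap` (N ≤ 8) provides the exact oracle for tests.

Both directed structures are used as-is — digraph flow and directional MT
are inherently asymmetric — with no symmetrization.

## Metrics

Accuracy is all-or-nothing per selection. WPM counts every selection,
correct or not, at 5 characters per word. WPM* removes every selection
whose source (previous selected key) or destination is space, subtracting
both characters and their movement times; this symmetric removal is the
default (a time-only variant would keep the character count — not
implemented as the symmetric form is the natural reading of "excluding
space transitions"). Wolpaw ITR uses
B = log₂N + P·log₂P + (1−P)·log₂((1−P)/(N−1)) bits per selection with
0·log 0 = 0, clamped to 0 below chance (P < 1/N) so rates stay
nonnegative; ITR = B × selections/min. Metrics are computed per session;
pooling selections across prompts gives the aggregate. Fitts-Digraph
Energy normalizes flow to probabilities and reports Σ p_ij·MT_ij in
seconds per character transition, comparable across corpora of different
sizes.

## Numerical choices and degenerate inputs

- OLS: R² defined as 0 when the MT variance is zero; slope 0 and invalid
  when all IDs coincide; empty bins yield NaN constants and invalid fits.
- Strict inequalities at both protocol thresholds (R² > 0.25 passes;
  residual > 3 SD flags).
- JSON artifacts are written with sorted keys and 6-decimal floats for
  byte-reproducibility; trial-log CSVs store full-precision floats so a
  replayed log refits the identical profile.
- Identical-point selection angles raise; zero-distance trials are the
  only place they can occur and are special-cased (bin −1).

## Problem sizes

The test and acceptance runs use the task's native sizes throughout (225-
to 400-target characterizations, 27-key layouts, 20-prompt evaluations);
oracle comparisons use 6-item QAP instances (720 permutations) and 100-user
cohorts for the personalization-benefit property.

## Known limitations

- The per-bin intercept identifiability limit described above.
- Piecewise-constant directional constants: no smoothing or interpolation
  across bin edges.
- The bundled phrase set is synthetic (authored for this package); digraph
  statistics approximate but do not reproduce any published phrase corpus.
- No modeling of word prediction, dynamic key sizing, or auxiliary keys
  (numbers, backspace, return).
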