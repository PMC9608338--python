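"""Multidirectional point-select task and directional Fitts' Law fitting.

The task presents a queue of targets on the honeycomb grid, chosen so that
movements of nine separation levels (0 to 8 key widths) and all 16 movement
directions are sampled.  Per direction bin, ordinary least squares of
movement time on index of difficulty yields direction-specific Fitts
constants (a, b).  An adaptive loop then re-presents targets for any bin
with too few trials, a weak MT-ID correlation, or unrepeated outliers,
until every bin passes or a hard cap on presented targets is reached.

The product is a :class:`FittsProfile`: one (a, b, R^2, n) row per angular
bin, which downstream layout generation samples to predict movement times
between candidate key positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    AngularBinScheme,
    GridSpec,
    KeyPosition,
    bin_of,
    euclidean,
    index_of_difficulty,
    selection_angle,
)
from .user_sim import UserModel, simulate_selection

__all__ = [
    "SeedConfig",
    "TrialRecord",
    "FittsFit",
    "FittsProfile",
    "seed_queue",
    "plan_next_target",
    "fit_bin",
    "detect_outliers",
    "run_characterization",
    "sample_constants",
]

#: separation levels used when re-presenting targets for a bin that fails
#: the fit criteria: one short, one medium and one long movement, spreading
#: index-of-difficulty support across its range.
REPEAT_LEVELS = (1, 4, 8)


@dataclass(frozen=True)
class SeedConfig:
    """Parameters of the characterization task.

    The defaults reproduce the standard protocol: nine separation levels
    (0-8 key widths), 25 targets seeded per level (225 total), a hard cap
    of 400 presented targets, at least 10 trials per direction bin, an
    R^2 > 0.25 requirement per bin, and a +/-3-SD outlier rule.
    """

    n_levels: int = 9
    per_level: int = 25
    max_targets: int = 400
    min_per_bin: int = 10
    r2_threshold: float = 0.25
    outlier_sd: float = 3.0
    rng_seed: int = 0
    include_zero_in_bins: bool = False

    def __post_init__(self) -> None:
        if self.n_levels < 1 or self.per_level < 1:
            raise ValueError("n_levels and per_level must be positive")
        if self.n_levels * self.per_level > self.max_targets:
            raise ValueError("initial queue cannot exceed max_targets")
        if not (0 <= self.r2_threshold <= 1):
            raise ValueError("r2_threshold must lie in [0, 1]")
        if self.outlier_sd <= 0:
            raise ValueError("outlier_sd must be positive")


@dataclass(frozen=True)
class TrialRecord:
    """One target-selection attempt.

    Distance is the Euclidean distance between the sequential click points
    and movement time the travel time between the clicks.  ``bin`` is -1
    for zero-distance (same-key) trials, whose direction is undefined.
    """

    trial_id: int
    from_key: KeyPosition
    to_key: KeyPosition
    click_from: tuple[float, float]
    click_to: tuple[float, float]
    distance_px: float
    movement_time_s: float
    angle_deg: float | None
    bin: int
    id_bits: float
    n_click_attempts: int
    success: bool
    level: int


@dataclass(frozen=True)
class FittsFit:
    """OLS fit of movement time on index of difficulty for one direction bin."""

    bin: int
    a_s: float
    b_s_per_bit: float
    r2: float
    n: int
    residual_sd_s: float
    valid: bool


@dataclass(frozen=True)
class FittsProfile:
    """Per-direction Fitts' Law constants describing one user's 2D control."""

    scheme: AngularBinScheme
    grid: GridSpec
    fits: tuple[FittsFit, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.fits) != self.scheme.n_bins:
            raise ValueError("profile must contain exactly one fit per bin")
        if sorted(f.bin for f in self.fits) != list(range(self.scheme.n_bins)):
            raise ValueError("each bin must appear exactly once")

    def fit_for(self, k: int) -> FittsFit:
        return self.fits[k]

    def valid_bins(self) -> list[int]:
        return [f.bin for f in self.fits if f.valid]

    def mean_valid_a(self) -> float:
        """Mean intercept over valid bins — the zero-distance re-selection time."""
        bins = self.valid_bins()
        if not bins:
            raise ValueError("profile has no valid bins")
        return float(np.mean([self.fits[k].a_s for k in bins]))

    @classmethod
    def from_constants(
        cls,
        a_s: np.ndarray,
        b_s_per_bit: np.ndarray,
        scheme: AngularBinScheme | None = None,
        grid: GridSpec | None = None,
        provenance: str = "constructed from known constants",
    ) -> "FittsProfile":
        """Build a profile directly from known per-bin constants (all valid)."""
        scheme = scheme or AngularBinScheme()
        grid = grid or GridSpec()
        fits = tuple(
            FittsFit(k, float(a_s[k]), float(b_s_per_bit[k]), 1.0, 0, 0.0, True)
            for k in range(scheme.n_bins)
        )
        return cls(scheme=scheme, grid=grid, fits=fits, provenance=provenance)


# ---------------------------------------------------------------------------
# target queue and planning


def seed_queue(cfg: SeedConfig) -> list[int]:
    """Randomized initial queue of separation levels.

    Contains ``per_level`` copies of each level 0..n_levels-1, uniformly
    shuffled by ``cfg.rng_seed`` (225 targets with the defaults).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    queue = np.repeat(np.arange(cfg.n_levels), cfg.per_level)
    rng.shuffle(queue)
    return [int(v) for v in queue]


def plan_next_target(
    grid: GridSpec,
    prev_key: KeyPosition,
    level: int,
    coverage,
    rng: np.random.Generator,
    scheme: AngularBinScheme = AngularBinScheme(),
) -> KeyPosition:
    """Choose the next target key realizing a separation level from ``prev_key``.

    Level 0 re-selects the same key (zero-distance trial).  Otherwise the
    planner considers keys whose center distance from ``prev_key`` lies
    within +/-0.5 W of ``level * W``, widening the window in 0.25-W steps if
    no key qualifies, and among candidates prefers those whose selection
    angle falls in the least-covered direction bin (``coverage`` is the
    per-bin trial count); remaining ties break uniformly at random.

    Raises
    ------
    ValueError
        If the grid has a single key and ``level > 0``.
    """
    if level == 0:
        return prev_key
    keys = [k for k in grid.all_keys() if (k.row, k.col) != (prev_key.row, prev_key.col)]
    if not keys:
        raise ValueError("cannot plan a nonzero-distance target on a single-key grid")
    w = grid.key_width_px
    target_d = level * w
    dists = np.array([euclidean(prev_key.center, k.center) for k in keys])
    window = 0.5 * w
    candidates: list[int] = []
    while not candidates:
        candidates = [i for i in range(len(keys)) if abs(dists[i] - target_d) <= window]
        window += 0.25 * w
    coverage = np.asarray(coverage)
    cand_bins = [bin_of(selection_angle(prev_key.center, keys[i].center), scheme) for i in candidates]
    best = min(coverage[b] for b in cand_bins)
    shortlist = [i for i, b in zip(candidates, cand_bins) if coverage[b] == best]
    return keys[shortlist[rng.integers(len(shortlist))]]


# ---------------------------------------------------------------------------
# regression


def fit_bin(trials, cfg: SeedConfig, bin_index: int | None = None) -> FittsFit:
    """Ordinary least squares of movement time on index of difficulty.

    Computed from the normal equations: b = Sxy/Sxx, a = mean(MT) - b*mean(ID),
    R^2 = 1 - SSres/SStot.  Degenerate cases: an empty bin yields an invalid
    fit with NaN constants; identical IDs or constant MT yield R^2 = 0.
    The fit is valid when n >= min_per_bin, the IDs take at least two
    distinct values, and R^2 strictly exceeds the threshold.
    """
    trials = list(trials)
    k = bin_index if bin_index is not None else (trials[0].bin if trials else -1)
    n = len(trials)
    if n == 0:
        return FittsFit(k, float("nan"), float("nan"), 0.0, 0, float("nan"), False)
    x = np.array([t.id_bits for t in trials])
    y = np.array([t.movement_time_s for t in trials])
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:  # all IDs identical: slope unidentifiable
        resid = y - ym
        sd = math.sqrt(float(np.sum(resid**2)) / max(n - 2, 1))
        return FittsFit(k, float(ym), 0.0, 0.0, n, sd, False)
    b = float(np.sum((x - xm) * (y - ym)) / sxx)
    a = float(ym - b * xm)
    resid = y - (a + b * x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 0.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    sd = math.sqrt(ss_res / max(n - 2, 1))
    valid = n >= cfg.min_per_bin and r2 > cfg.r2_threshold
    return FittsFit(k, a, b, r2, n, sd, valid)


def detect_outliers(fit: FittsFit, trials, outlier_sd: float = 3.0) -> list[TrialRecord]:
    """Trials whose residual from the fitted line exceeds the outlier band.

    A trial is an outlier when |MT - (a + b*ID)| strictly exceeds
    ``outlier_sd`` residual standard deviations (the band edge itself is not
    flagged).  An invalid fit flags nothing.
    """
    # residual SDs at floating-point roundoff level mean an exact fit
    if not fit.valid or not math.isfinite(fit.residual_sd_s) or fit.residual_sd_s < 1e-12:
        return []
    band = outlier_sd * fit.residual_sd_s
    return [
        t
        for t in trials
        if abs(t.movement_time_s - (fit.a_s + fit.b_s_per_bit * t.id_bits)) > band
    ]


# ---------------------------------------------------------------------------
# the adaptive task


def run_characterization(
    user: UserModel,
    grid: GridSpec | None = None,
    scheme: AngularBinScheme | None = None,
    cfg: SeedConfig | None = None,
) -> tuple[FittsProfile, list[TrialRecord]]:
    """Run the full adaptive point-select task against a simulated user.

    Presents the seeded queue, fits every direction bin, then repeatedly
    appends repeat targets for bins that fail the acceptance predicate
    (n >= min_per_bin and R^2 > threshold) or hold outliers not yet
    re-presented, stopping when all bins pass or exactly at the
    ``max_targets`` cap.

    Returns the fitted profile and the complete trial log.
    """
    grid = grid or GridSpec()
    scheme = scheme or AngularBinScheme()
    cfg = cfg or SeedConfig()

    plan_rng = np.random.default_rng([cfg.rng_seed, 1])
    user_rng = np.random.default_rng(user.rng_seed)
    w = grid.key_width_px
    n_bins = scheme.n_bins

    trials: list[TrialRecord] = []
    coverage = np.zeros(n_bins, dtype=int)
    current = grid.center_key()

    def present(level: int, coverage_vec) -> None:
        nonlocal current
        target = (
            current
            if level == 0
            else plan_next_target(grid, current, level, coverage_vec, plan_rng, scheme)
        )
        d = euclidean(current.center, target.center)
        mt, success, attempts = simulate_selection(user, current.center, target.center, w, user_rng)
        if d > 0:
            ang = selection_angle(current.center, target.center)
            k = bin_of(ang, scheme)
            coverage[k] += 1
        else:
            ang, k = None, -1
        trials.append(
            TrialRecord(
                trial_id=len(trials),
                from_key=current,
                to_key=target,
                click_from=current.center,
                click_to=target.center,
                distance_px=d,
                movement_time_s=mt,
                angle_deg=ang,
                bin=k,
                id_bits=index_of_difficulty(d, w),
                n_click_attempts=attempts,
                success=success,
                level=level,
            )
        )
        current = target

    for level in seed_queue(cfg):
        present(level, coverage)

    big = 10**9  # sentinel coverage steering repeats toward one bin

    while len(trials) < cfg.max_targets:
        fits, by_bin = _fit_all_bins(trials, cfg, n_bins)
        repeats: list[tuple[int, int]] = []
        for k in range(n_bins):
            if not fits[k].valid:
                repeats.extend((k, lvl) for lvl in REPEAT_LEVELS)
            else:
                for out in detect_outliers(fits[k], by_bin[k], cfg.outlier_sd):
                    repeated = any(
                        t.bin == k and t.level == out.level and t.trial_id > out.trial_id
                        for t in by_bin[k]
                    )
                    if not repeated:
                        repeats.append((k, out.level))
        if not repeats:
            break
        for k, lvl in repeats[: cfg.max_targets - len(trials)]:
            steer = np.full(n_bins, big)
            steer[k] = 0
            present(max(lvl, 1), steer)

    fits, _ = _fit_all_bins(trials, cfg, n_bins)
    profile = FittsProfile(
        scheme=scheme,
        grid=grid,
        fits=tuple(fits),
        provenance=f"simulated characterization; task seed {cfg.rng_seed}, "
        f"user seed {user.rng_seed}, {len(trials)} targets presented",
    )
    return profile, trials


def _fit_all_bins(trials, cfg: SeedConfig, n_bins: int):
    by_bin: dict[int, list[TrialRecord]] = {k: [] for k in range(n_bins)}
    zeros = [t for t in trials if t.bin < 0]
    for t in trials:
        if t.bin >= 0:
            by_bin[t.bin].append(t)
    if cfg.include_zero_in_bins:
        for k in range(n_bins):
            by_bin[k] = by_bin[k] + zeros
    fits = [fit_bin(by_bin[k], cfg, bin_index=k) for k in range(n_bins)]
    return fits, by_bin


# ---------------------------------------------------------------------------
# sampling the profile


def sample_constants(profile: FittsProfile, angle_deg: float) -> tuple[float, float]:
    """Fitts constants (a, b) for a movement at ``angle_deg``.

    Piecewise-constant over bins: returns the containing bin's constants if
    its fit is valid; otherwise falls back to the nearest valid bin by
    circular distance, averaging the constants of the two neighbors when
    they are equidistant.

    Raises
    ------
    ValueError
        If the profile has no valid bins at all.
    """
    valid = profile.valid_bins()
    if not valid:
        raise ValueError("profile has no valid bins; cannot sample constants")
    k = bin_of(angle_deg, profile.scheme)
    fit = profile.fits[k]
    if fit.valid:
        return fit.a_s, fit.b_s_per_bit
    dists = {j: profile.scheme.circular_bin_distance(k, j) for j in valid}
    dmin = min(dists.values())
    nearest = [j for j, d in dists.items() if d == dmin]
    a = float(np.mean([profile.fits[j].a_s for j in nearest]))
    b = float(np.mean([profile.fits[j].b_s_per_bit for j in nearest]))
    return a, b
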