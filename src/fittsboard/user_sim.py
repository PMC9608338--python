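"""Synthetic point-select users for testing the personalization pipeline.

A :class:`UserModel` holds ground-truth direction-specific Fitts' Law
constants: movement time for a selection at angle theta and distance D is

    MT = a*(bin(theta)) + b*(bin(theta)) * log2(D/W + 1) + eps,

with ``eps ~ Normal(0, noise_sd_s)`` and a floor preventing non-physical
draws.  Selections can also miss with a fixed per-attempt probability.  The
model stands in for a human participant so that movement characterization,
layout generation and transcription evaluation are all testable end to end.

Two miss semantics are exposed, matching the two tasks:

* characterization gives unlimited chances per target, so
  :func:`simulate_selection` retries until success and each failed attempt
  costs an independent movement-time draw (re-homing);
* transcription continues without correction, so in
  :func:`simulate_transcription` a miss selects a uniformly random adjacent
  key and the walk carries on from there.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    AngularBinScheme,
    bin_of,
    euclidean,
    index_of_difficulty,
    selection_angle,
)

__all__ = ["UserModel", "Selection", "SessionLog", "simulate_selection", "simulate_transcription"]


@dataclass(frozen=True)
class UserModel:
    """Ground-truth directional movement model of one synthetic participant.

    ``a_s`` and ``b_s_per_bit`` are per-angular-bin arrays (seconds and
    seconds/bit).  Zero-distance re-selections have no direction, so they
    use the mean of ``a_s`` across bins as the reaction-time floor.
    """

    a_s: np.ndarray
    b_s_per_bit: np.ndarray
    noise_sd_s: float = 0.0
    miss_prob: float = 0.0
    mt_floor_s: float = 0.05
    rng_seed: int = 0
    scheme: AngularBinScheme = field(default_factory=AngularBinScheme)

    def __post_init__(self) -> None:
        a = np.asarray(self.a_s, dtype=float)
        b = np.asarray(self.b_s_per_bit, dtype=float)
        object.__setattr__(self, "a_s", a)
        object.__setattr__(self, "b_s_per_bit", b)
        n = self.scheme.n_bins
        if a.shape != (n,) or b.shape != (n,):
            raise ValueError(f"per-bin constants must have shape ({n},)")
        if (a < 0).any() or (b < 0).any():
            raise ValueError("Fitts constants must be nonnegative")
        if self.noise_sd_s < 0:
            raise ValueError("noise_sd_s must be nonnegative")
        if not (0 <= self.miss_prob < 1):
            raise ValueError("miss_prob must lie in [0, 1)")

    # -- constructors -------------------------------------------------

    @classmethod
    def isotropic(cls, a_s: float, b_s_per_bit: float, **kw) -> "UserModel":
        scheme = kw.pop("scheme", AngularBinScheme())
        n = scheme.n_bins
        return cls(np.full(n, a_s), np.full(n, b_s_per_bit), scheme=scheme, **kw)

    @classmethod
    def random_directional(
        cls,
        rng: np.random.Generator,
        a_range: tuple[float, float] = (0.3, 1.3),
        b_range: tuple[float, float] = (0.4, 1.4),
        **kw,
    ) -> "UserModel":
        """Per-bin constants drawn uniformly from the given ranges."""
        scheme = kw.pop("scheme", AngularBinScheme())
        n = scheme.n_bins
        a = rng.uniform(*a_range, size=n)
        b = rng.uniform(*b_range, size=n)
        return cls(a, b, scheme=scheme, **kw)

    @classmethod
    def anisotropic(
        cls,
        rng: np.random.Generator,
        slow_factor: float = 3.0,
        a_s: float = 0.5,
        b_fast: float = 0.5,
        **kw,
    ) -> "UserModel":
        """A user whose slope b is ``slow_factor`` times larger in one
        randomly oriented half-plane — e.g. someone who moves easily to one
        side but struggles toward the other."""
        scheme = kw.pop("scheme", AngularBinScheme())
        n = scheme.n_bins
        axis = rng.uniform(0.0, 360.0)
        centers = np.asarray(scheme.centers_deg)
        diff = np.abs((centers - axis + 180.0) % 360.0 - 180.0)
        b = np.where(diff <= 90.0, b_fast, b_fast * slow_factor)
        return cls(np.full(n, a_s), b, scheme=scheme, **kw)

    # -- deterministic expectations -----------------------------------

    def zero_distance_a(self) -> float:
        """Reaction-time intercept for a same-key re-selection (mean over bins)."""
        return float(np.mean(self.a_s))

    def expected_mt(self, p_from, p_to, key_width_px: float) -> float:
        """Noise-free movement time between two pixel points."""
        d = euclidean(p_from, p_to)
        if d == 0.0:
            return max(self.mt_floor_s, self.zero_distance_a())
        k = bin_of(selection_angle(p_from, p_to), self.scheme)
        mt = self.a_s[k] + self.b_s_per_bit[k] * index_of_difficulty(d, key_width_px)
        return max(self.mt_floor_s, mt)

    def mt_matrix(self, positions, key_width_px: float) -> np.ndarray:
        """True expected movement-time matrix over a list of key positions.

        This is the ground-truth analogue of the fitted movement-time matrix
        used for layout generation; it is what an oracle evaluation of a
        layout's expected transcription time uses.
        """
        m = len(positions)
        out = np.empty((m, m))
        for i, p in enumerate(positions):
            for j, q in enumerate(positions):
                out[i, j] = self.expected_mt(p.center, q.center, key_width_px)
        return out


def _draw_mt(user: UserModel, p_from, p_to, key_width_px: float, rng: np.random.Generator) -> float:
    """One noisy movement-time draw for a single click attempt."""
    d = euclidean(p_from, p_to)
    if d == 0.0:
        mean = user.zero_distance_a()
    else:
        k = bin_of(selection_angle(p_from, p_to), user.scheme)
        mean = user.a_s[k] + user.b_s_per_bit[k] * index_of_difficulty(d, key_width_px)
    eps = rng.normal(0.0, user.noise_sd_s) if user.noise_sd_s > 0 else 0.0
    return max(user.mt_floor_s, mean + eps)


def simulate_selection(
    user: UserModel,
    p_from,
    p_to,
    key_width_px: float,
    rng: np.random.Generator | None = None,
) -> tuple[float, bool, int]:
    """Simulate one unlimited-chances target selection.

    Each attempt fails independently with ``miss_prob``; a failed attempt
    costs a fresh movement-time draw and the user tries again, so the
    attempt count is geometric with mean 1/(1 - miss_prob).  Returns
    ``(total_movement_time_s, success, n_click_attempts)`` with success
    always True (the target is eventually hit).
    """
    if rng is None:
        rng = np.random.default_rng(user.rng_seed)
    total = _draw_mt(user, p_from, p_to, key_width_px, rng)
    attempts = 1
    while user.miss_prob > 0 and rng.random() < user.miss_prob:
        total += _draw_mt(user, p_from, p_to, key_width_px, rng)
        attempts += 1
    return total, True, attempts


@dataclass(frozen=True)
class Selection:
    """One key selection during transcription."""

    intended: str
    selected: str
    movement_time_s: float
    success: bool


@dataclass(frozen=True)
class SessionLog:
    """A transcription session: the prompt and every selection made."""

    prompt: str
    selections: tuple[Selection, ...]

    @property
    def total_time_s(self) -> float:
        return float(sum(s.movement_time_s for s in self.selections))

    @property
    def n_selections(self) -> int:
        return len(self.selections)


def _adjacent_keys(layout, key, tol: float = 1.05):
    """Layout keys within ~one key width of ``key`` (its hex neighbors)."""
    w = layout.grid.key_width_px
    out = [
        (ch, k)
        for ch, k in sorted(layout.assignment.items())
        if k != key and euclidean(k.center, key.center) <= tol * w
    ]
    if not out:  # isolated key: fall back to the nearest other key
        ch, k = min(
            ((ch, k) for ch, k in sorted(layout.assignment.items()) if k != key),
            key=lambda item: euclidean(item[1].center, key.center),
        )
        out = [(ch, k)]
    return out


def simulate_transcription(
    user: UserModel,
    layout,
    prompt: str,
    rng: np.random.Generator | None = None,
) -> SessionLog:
    """Simulate spelling ``prompt`` on ``layout`` without error correction.

    The cursor homes on the layout's centroid key, then visits each prompt
    character in turn.  Each selection is a single attempt: with probability
    ``miss_prob`` the click lands on a uniformly random adjacent key instead,
    and the walk continues from wherever the click landed — mirroring a
    transcription task in which mistakes are not corrected.

    Raises
    ------
    KeyError
        If a normalized prompt character is not on the layout.
    """
    from .text import normalize_text

    if rng is None:
        rng = np.random.default_rng(user.rng_seed)
    text = normalize_text(prompt)
    w = layout.grid.key_width_px

    for ch in text:
        if ch not in layout.assignment:
            raise KeyError(f"prompt character {ch!r} is not on the layout")

    current = layout.centroid_key()
    selections: list[Selection] = []
    for ch in text:
        target = layout.assignment[ch]
        mt = _draw_mt(user, current.center, target.center, w, rng)
        miss = user.miss_prob > 0 and rng.random() < user.miss_prob
        if miss:
            neighbors = _adjacent_keys(layout, target)
            sel_ch, sel_key = neighbors[rng.integers(len(neighbors))]
            selections.append(Selection(ch, sel_ch, mt, False))
            current = sel_key
        else:
            selections.append(Selection(ch, ch, mt, True))
            current = target
    return SessionLog(prompt=text, selections=tuple(selections))
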