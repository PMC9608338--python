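"""Communication-performance metrics for transcription sessions and layouts.

* accuracy — per-selection all-or-nothing: percent of selections that hit
  the intended key.
* WPM — (characters per minute) / 5, counting every selection, correct or
  not, with the conventional 5-characters-per-word divisor.
* WPM* — WPM recomputed after removing every selection into or out of the
  space key (both its character and its movement time), isolating letter
  movement speed from space-key placement.
* Wolpaw ITR — information transfer rate in bits/min:
  B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)) bits per selection for
  N possible targets at accuracy P, times the selection rate.  B is
  floored at 0 below chance so rates stay nonnegative.
* Fitts-Digraph Energy — the expected movement time per character
  transition of a layout, sum_ij p_ij * MT_ij with digraph probabilities
  p_ij; the "computational keyboard efficiency" covariate (lower is
  better).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .characterization import FittsProfile
from .layout_gen import Layout, MTMatrix, build_mt_matrix, generic_mt_matrix
from .text import Alphabet
from .user_sim import SessionLog

__all__ = [
    "MetricsReport",
    "wpm",
    "wpm_star",
    "accuracy",
    "wolpaw_bits_per_selection",
    "wolpaw_itr",
    "fitts_digraph_energy",
    "evaluate_session",
]

DEFAULT_N_TARGETS = 27


@dataclass(frozen=True)
class MetricsReport:
    """Aggregate communication metrics for one session."""

    accuracy_pct: float
    wpm: float
    wpm_star: float | None
    itr_bits_per_min: float
    n_selections: int
    n_targets_possible: int
    energy_s_per_char: float | None = None


def wpm(session: SessionLog) -> float:
    """Words per minute: (selections per minute) / 5, errors included.

    Raises
    ------
    ValueError
        If the session has zero duration.
    """
    if session.total_time_s <= 0:
        raise ValueError("cannot compute a rate over a zero-duration session")
    return (session.n_selections / (session.total_time_s / 60.0)) / 5.0


def wpm_star(session: SessionLog, space_char: str = " ") -> float:
    """WPM excluding every selection whose source or destination is space.

    The source of a selection is the previously *selected* key (the first
    selection has no source and is kept unless it targets space); removed
    selections contribute neither characters nor movement time.

    Raises
    ------
    ValueError
        If nothing remains after removing space transitions.
    """
    kept_n = 0
    kept_time = 0.0
    prev_selected: str | None = None
    for sel in session.selections:
        involves_space = sel.selected == space_char or prev_selected == space_char
        if not involves_space:
            kept_n += 1
            kept_time += sel.movement_time_s
        prev_selected = sel.selected
    if kept_n == 0 or kept_time <= 0:
        raise ValueError("no non-space selections left; WPM* undefined")
    return (kept_n / (kept_time / 60.0)) / 5.0


def accuracy(session: SessionLog) -> float:
    """Percent of selections that hit the intended target (all-or-nothing).

    Raises
    ------
    ValueError
        If the session contains no selections.
    """
    if session.n_selections == 0:
        raise ValueError("accuracy undefined for an empty session")
    hits = sum(1 for s in session.selections if s.success)
    return 100.0 * hits / session.n_selections


def wolpaw_bits_per_selection(p: float, n_targets: int) -> float:
    """Wolpaw bits per selection for accuracy ``p`` over ``n_targets`` choices.

    B = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)), with 0 log 0 = 0 and
    B clamped at 0 when P falls below chance (1/N).

    Raises
    ------
    ValueError
        If ``n_targets`` < 2 or ``p`` outside [0, 1].
    """
    if n_targets < 2:
        raise ValueError("need at least two possible targets")
    if not (0.0 <= p <= 1.0):
        raise ValueError("accuracy must lie in [0, 1]")
    if p < 1.0 / n_targets:  # below chance: the formula turns back up, clamp
        return 0.0
    b = math.log2(n_targets)
    if p > 0.0:
        b += p * math.log2(p)
    if p < 1.0:
        b += (1.0 - p) * math.log2((1.0 - p) / (n_targets - 1))
    return max(0.0, b)


def wolpaw_itr(session: SessionLog, n_targets: int = DEFAULT_N_TARGETS) -> float:
    """Wolpaw information transfer rate in bits/min for a session."""
    if session.total_time_s <= 0:
        raise ValueError("cannot compute a rate over a zero-duration session")
    p = accuracy(session) / 100.0
    rate_per_min = session.n_selections / (session.total_time_s / 60.0)
    return wolpaw_bits_per_selection(p, n_targets) * rate_per_min


def fitts_digraph_energy(
    layout: Layout,
    flow: np.ndarray,
    movement: FittsProfile | MTMatrix | None = None,
    alphabet: Alphabet = Alphabet(),
    mt_floor_s: float = 0.05,
) -> float:
    """Expected seconds per character transition of ``layout`` under ``flow``.

    ``movement`` selects the model for predicted movement times between the
    layout's key positions: a fitted :class:`FittsProfile`, a precomputed
    :class:`MTMatrix` over exactly the layout's positions in alphabet
    order, or None for the generic isotropic constants.  Flow is normalized
    to probabilities, so corpora of different sizes are comparable.

    Raises
    ------
    ValueError
        If the flow is all zero or the layout misses alphabet characters.
    """
    flow = np.asarray(flow, dtype=float)
    n = len(alphabet)
    if flow.shape != (n, n):
        raise ValueError(f"flow must be {n}x{n} to match the alphabet")
    total = flow.sum()
    if total <= 0:
        raise ValueError("flow is all zero; energy undefined")
    for ch in alphabet:
        if ch not in layout.assignment:
            raise ValueError(f"layout does not place character {ch!r}")

    positions = tuple(layout.assignment[ch] for ch in alphabet)
    w = layout.grid.key_width_px
    if movement is None:
        mt = generic_mt_matrix(positions, w, mt_floor_s=mt_floor_s).matrix
    elif isinstance(movement, FittsProfile):
        mt = build_mt_matrix(movement, positions, w, mt_floor_s=mt_floor_s).matrix
    elif isinstance(movement, MTMatrix):
        if tuple(movement.positions) != positions:
            raise ValueError("MTMatrix positions must match the layout's alphabet order")
        mt = movement.matrix
    else:
        raise TypeError("movement must be a FittsProfile, MTMatrix or None")
    p = flow / total
    return float(np.sum(p * mt))


def evaluate_session(
    session: SessionLog,
    layout: Layout | None = None,
    flow: np.ndarray | None = None,
    movement=None,
    n_targets: int = DEFAULT_N_TARGETS,
) -> MetricsReport:
    """All session metrics in one report; energy only when layout+flow given."""
    energy = None
    if layout is not None and flow is not None:
        energy = fitts_digraph_energy(layout, flow, movement)
    star: float | None
    try:
        star = wpm_star(session)
    except ValueError:
        star = None
    return MetricsReport(
        accuracy_pct=accuracy(session),
        wpm=wpm(session),
        wpm_star=star,
        itr_bits_per_min=wolpaw_itr(session, n_targets),
        n_selections=session.n_selections,
        n_targets_possible=n_targets,
        energy_s_per_char=energy,
    )
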