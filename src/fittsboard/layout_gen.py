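"""Keyboard layout generation as a quadratic assignment problem.

Placing the 27 characters (A-Z plus space) on candidate key positions is a
QAP: minimize E(pi) = sum_ij f[i,j] * d[pi(i), pi(j)], where the flow
f[i,j] counts digraph transitions from character i to character j in a
corpus, and the distance d[p,q] is the predicted movement time from key
position p to key position q.  For a *personalized* layout, d comes from
the user's directional Fitts profile and is generally asymmetric; for the
*generically optimized* layout it comes from isotropic literature constants
(a = 0.127 s, b = 1/4.9 s/bit).  A fixed QWERTY arrangement (space placed
right of "M") serves as the conventional baseline.

The solver is scipy's Fast Approximate QAP (graph-matching) procedure,
restarted from the barycenter plus random doubly-stochastic initializations
and keeping the lowest-energy permutation.  A brute-force enumerator over
tiny instances serves as an exact oracle in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import quadratic_assignment

from .characterization import FittsProfile, sample_constants
from .geometry import (
    GridSpec,
    KeyPosition,
    euclidean,
    index_of_difficulty,
    selection_angle,
)
from .text import Alphabet, normalize_text

__all__ = [
    "GENERIC_A_S",
    "GENERIC_B_S_PER_BIT",
    "MTMatrix",
    "Layout",
    "count_digraphs",
    "candidate_positions",
    "build_mt_matrix",
    "generic_mt_matrix",
    "qap_energy",
    "solve_qap",
    "brute_force_qap",
    "generic_layout",
    "qwerty_layout",
]

# Literature constants for generic cursor movement: delay a and 1/throughput b.
GENERIC_A_S = 0.127
GENERIC_B_S_PER_BIT = 1.0 / 4.9

DEFAULT_MT_FLOOR_S = 0.05


@dataclass(frozen=True)
class MTMatrix:
    """Predicted movement times (seconds) between candidate key positions.

    ``matrix[p, q]`` is the predicted time to move from position p to
    position q; the diagonal holds the same-key re-selection time.  With a
    directional profile the matrix is generally asymmetric.
    """

    matrix: np.ndarray
    positions: tuple[KeyPosition, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "positions", tuple(self.positions))
        if m.shape != (len(self.positions), len(self.positions)):
            raise ValueError("matrix shape must match the number of positions")


@dataclass(frozen=True)
class Layout:
    """An assignment of characters to key positions on a grid."""

    assignment: dict[str, KeyPosition]
    grid: GridSpec
    label: str = ""
    energy: float | None = None

    def __post_init__(self) -> None:
        spots = [(k.row, k.col) for k in self.assignment.values()]
        if len(set(spots)) != len(spots):
            raise ValueError("layout positions must be distinct")

    @property
    def chars(self) -> str:
        return "".join(sorted(self.assignment))

    def position_of(self, ch: str) -> KeyPosition:
        return self.assignment[ch]

    def centroid_key(self) -> KeyPosition:
        """The key nearest the mean of all key centers (the homing key)."""
        centers = np.array([k.center for k in self.assignment.values()])
        mid = centers.mean(axis=0)
        return min(
            (self.assignment[ch] for ch in sorted(self.assignment)),
            key=lambda k: euclidean(k.center, tuple(mid)),
        )


# ---------------------------------------------------------------------------
# flow


def count_digraphs(corpus: str, alphabet: Alphabet = Alphabet()) -> np.ndarray:
    """Digraph transition counts over the alphabet (rows = from, cols = to).

    The corpus is normalized (uppercased, whitespace runs collapsed to one
    space); characters outside the alphabet are dropped and break adjacency,
    so the digraph straddling a dropped character is not counted.  Adjacent
    repeats (double letters) count on the diagonal of character pairs.
    """
    n = len(alphabet)
    idx = {ch: i for i, ch in enumerate(alphabet)}
    flow = np.zeros((n, n), dtype=float)
    prev: int | None = None
    for ch in normalize_text(corpus):
        i = idx.get(ch)
        if i is None:
            prev = None
            continue
        if prev is not None:
            flow[prev, i] += 1
        prev = i
    return flow


# ---------------------------------------------------------------------------
# candidate positions and movement-time matrices


def candidate_positions(grid: GridSpec, m: int) -> tuple[KeyPosition, ...]:
    """The ``m`` grid keys of a compact hex-spiral footprint.

    Keys sorted by ascending distance from the grid's central key, ties by
    ascending selection angle from the center (the central key itself
    first).  Deterministic for a given grid and m.
    """
    if m < 1 or m > grid.rows * grid.cols:
        raise ValueError(f"m must lie in [1, {grid.rows * grid.cols}]")
    c = grid.center_key()

    def sort_key(k: KeyPosition):
        d = euclidean(c.center, k.center)
        ang = 0.0 if d == 0.0 else selection_angle(c.center, k.center)
        return (round(d, 9), round(ang, 9), k.row, k.col)

    return tuple(sorted(grid.all_keys(), key=sort_key)[:m])


def build_mt_matrix(
    profile: FittsProfile,
    positions,
    key_width_px: float,
    mt_floor_s: float = DEFAULT_MT_FLOOR_S,
) -> MTMatrix:
    """Predicted movement-time matrix from a directional Fitts profile.

    For each ordered pair of positions: (i) compute the selection angle,
    (ii) sample the profile's (a, b) for that angle, (iii) apply Fitts' Law
    with the pair's distance.  The diagonal is the zero-distance
    re-selection time, the mean intercept over valid bins.

    Raises
    ------
    ValueError
        If the profile has no valid bins.
    """
    positions = tuple(positions)
    m = len(positions)
    diag = max(mt_floor_s, profile.mean_valid_a())
    out = np.empty((m, m))
    for i, p in enumerate(positions):
        for j, q in enumerate(positions):
            if i == j:
                out[i, j] = diag
                continue
            d = euclidean(p.center, q.center)
            if d == 0.0:
                out[i, j] = diag
                continue
            a, b = sample_constants(profile, selection_angle(p.center, q.center))
            out[i, j] = max(mt_floor_s, a + b * index_of_difficulty(d, key_width_px))
    return MTMatrix(out, positions)


def generic_mt_matrix(
    positions,
    key_width_px: float,
    a_s: float = GENERIC_A_S,
    b_s_per_bit: float = GENERIC_B_S_PER_BIT,
    mt_floor_s: float = DEFAULT_MT_FLOOR_S,
) -> MTMatrix:
    """Isotropic movement-time matrix from fixed literature constants."""
    positions = tuple(positions)
    m = len(positions)
    out = np.empty((m, m))
    for i, p in enumerate(positions):
        for j, q in enumerate(positions):
            d = euclidean(p.center, q.center)
            out[i, j] = max(mt_floor_s, a_s + b_s_per_bit * index_of_difficulty(d, key_width_px))
    return MTMatrix(out, positions)


# ---------------------------------------------------------------------------
# solving


def qap_energy(flow: np.ndarray, dist: np.ndarray, perm: np.ndarray) -> float:
    """E(pi) = sum_ij flow[i,j] * dist[pi(i), pi(j)] for a permutation array."""
    perm = np.asarray(perm)
    return float(np.sum(flow * dist[np.ix_(perm, perm)]))


def _assignment_layout(
    perm, alphabet: Alphabet, positions, grid: GridSpec, label: str, energy: float
) -> Layout:
    assignment = {ch: positions[perm[i]] for i, ch in enumerate(alphabet)}
    return Layout(assignment=assignment, grid=grid, label=label, energy=energy)


def solve_qap(
    flow: np.ndarray,
    mt: MTMatrix,
    alphabet: Alphabet = Alphabet(),
    grid: GridSpec | None = None,
    restarts: int = 32,
    rng_seed: int = 0,
    label: str = "personalized",
) -> Layout:
    """Minimize layout energy with the Fast Approximate QAP procedure.

    Runs FAQ from the barycenter initialization plus ``restarts - 1``
    random permutation-matrix starts (the extreme points of the
    doubly-stochastic polytope, which diversify the search far better than
    near-barycenter perturbations) and keeps the permutation of lowest
    energy.  When there are more positions than characters the flow is
    zero-padded with dummy items whose placement is discarded, so the
    returned layout covers exactly the alphabet.

    Raises
    ------
    ValueError
        If there are fewer positions than characters.
    """
    flow = np.asarray(flow, dtype=float)
    n = len(alphabet)
    m = len(mt.positions)
    if flow.shape != (n, n):
        raise ValueError(f"flow must be {n}x{n} to match the alphabet")
    if n > m:
        raise ValueError("need at least as many candidate positions as characters")
    grid = grid or GridSpec()

    padded = np.zeros((m, m))
    padded[:n, :n] = flow
    dist = mt.matrix
    # the argmin is invariant to flow scale; solve on normalized flow so the
    # search trajectory (and hence the seeded result) is too
    total = padded.sum()
    solver_flow = padded / total if total > 0 else padded

    rng = np.random.default_rng(rng_seed)
    best_perm: np.ndarray | None = None
    best_e = np.inf
    eye = np.eye(m)
    for r in range(max(1, restarts)):
        p0 = "barycenter" if r == 0 else eye[rng.permutation(m)]
        res = quadratic_assignment(
            solver_flow,
            dist,
            method="faq",
            options={"P0": p0, "rng": rng, "maximize": False, "maxiter": 100, "tol": 1e-8},
        )
        e = qap_energy(padded, dist, res.col_ind)
        if e < best_e:
            best_e = e
            best_perm = np.asarray(res.col_ind)
    return _assignment_layout(best_perm, alphabet, mt.positions, grid, label, best_e)


def brute_force_qap(
    flow: np.ndarray,
    mt: MTMatrix,
    alphabet: Alphabet,
    grid: GridSpec | None = None,
    label: str = "brute-force",
) -> Layout:
    """Exact minimum-energy assignment by exhaustive enumeration.

    Requires equal item and position counts of at most 8 (guarding the
    factorial search).  Ties break by lexicographic permutation order, so
    the result is deterministic.
    """
    flow = np.asarray(flow, dtype=float)
    n = len(alphabet)
    m = len(mt.positions)
    if n != m:
        raise ValueError("brute force requires exactly as many positions as characters")
    if n > 8:
        raise ValueError("brute force limited to 8 items")
    grid = grid or GridSpec()
    dist = mt.matrix
    best_perm = None
    best_e = np.inf
    for perm in itertools.permutations(range(n)):
        e = qap_energy(flow, dist, np.array(perm))
        if e < best_e:  # strict: first (lexicographically smallest) optimum wins
            best_e = e
            best_perm = np.array(perm)
    return _assignment_layout(best_perm, alphabet, mt.positions, grid, label, best_e)


def generic_layout(
    flow: np.ndarray,
    positions,
    key_width_px: float,
    alphabet: Alphabet = Alphabet(),
    grid: GridSpec | None = None,
    restarts: int = 32,
    rng_seed: int = 0,
) -> Layout:
    """Generically optimized layout: QAP under isotropic literature constants."""
    mt = generic_mt_matrix(positions, key_width_px)
    return solve_qap(
        flow, mt, alphabet=alphabet, grid=grid, restarts=restarts, rng_seed=rng_seed,
        label="generic-optimized",
    )


_QWERTY_ROWS = ("QWERTYUIOP", "ASDFGHJKL", "ZXCVBNM ")


def qwerty_layout(grid: GridSpec | None = None) -> Layout:
    """The fixed QWERTY baseline with the space key right of "M".

    Three rows (QWERTYUIOP / ASDFGHJKL / ZXCVBNM + space) of equal-width
    keys placed on the top-left of the grid.

    Raises
    ------
    ValueError
        If the grid has fewer than 10 columns or 3 rows.
    """
    grid = grid or GridSpec(rows=3, cols=10)
    if grid.cols < 10 or grid.rows < 3:
        raise ValueError("QWERTY needs a grid of at least 3 rows x 10 columns")
    assignment = {
        ch: grid.key(r, c)
        for r, row in enumerate(_QWERTY_ROWS)
        for c, ch in enumerate(row)
    }
    return Layout(assignment=assignment, grid=grid, label="qwerty")
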