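"""Point-select task: queue, planner, per-bin OLS fits, adaptive loop."""

import math

import numpy as np
import pytest

import fittsboard as fb
from fittsboard.characterization import (
    FittsFit,
    FittsProfile,
    SeedConfig,
    TrialRecord,
    detect_outliers,
    fit_bin,
    plan_next_target,
    run_characterization,
    sample_constants,
    seed_queue,
)
from fittsboard.geometry import euclidean


def make_trial(id_bits, mt, bin_=0, trial_id=0, level=1):
    """Minimal trial for regression tests; geometry fields are dummies."""
    key = fb.GridSpec().key(0, 0)
    return TrialRecord(
        trial_id=trial_id, from_key=key, to_key=key, click_from=(0, 0), click_to=(0, 0),
        distance_px=0.0, movement_time_s=mt, angle_deg=0.0, bin=bin_,
        id_bits=id_bits, n_click_attempts=1, success=True, level=level,
    )


class TestSeedQueue:
    def test_default_queue_has_225_targets_25_per_level(self):
        q = seed_queue(SeedConfig())
        assert len(q) == 225
        for level in range(9):
            assert q.count(level) == 25

    def test_tiny_queue(self):
        assert seed_queue(SeedConfig(n_levels=1, per_level=3, max_targets=3)) == [0, 0, 0]

    def test_shuffle_determinism(self):
        a = seed_queue(SeedConfig(rng_seed=5))
        b = seed_queue(SeedConfig(rng_seed=5))
        c = seed_queue(SeedConfig(rng_seed=6))
        assert a == b
        assert a != c


class TestPlanner:
    def test_level_zero_reselects_same_key(self, grid, scheme):
        rng = np.random.default_rng(0)
        center = grid.center_key()
        assert plan_next_target(grid, center, 0, np.zeros(16), rng, scheme) == center

    def test_level_one_from_center_is_an_adjacent_key(self, grid, scheme):
        # brute-force the feasible set: keys with |dist - W| <= 0.5 W
        center = grid.center_key()
        w = grid.key_width_px
        feasible = {
            (k.row, k.col)
            for k in grid.all_keys()
            if abs(euclidean(center.center, k.center) - w) <= 0.5 * w
        }
        assert len(feasible) == 6  # hex ring
        rng = np.random.default_rng(1)
        for _ in range(20):
            k = plan_next_target(grid, center, 1, np.zeros(16), rng, scheme)
            assert (k.row, k.col) in feasible

    def test_level_eight_from_corner_reaches_far_edge(self, grid, scheme):
        corner = grid.key(0, 0)
        w = grid.key_width_px
        rng = np.random.default_rng(2)
        k = plan_next_target(grid, corner, 8, np.zeros(16), rng, scheme)
        # brute-force scan: the best achievable window around 8 W
        dists = [euclidean(corner.center, q.center) for q in grid.all_keys()]
        assert max(dists) >= 7.5 * w  # far corner is reachable
        assert euclidean(corner.center, k.center) >= 7.5 * w

    def test_prefers_least_covered_bin(self, grid, scheme):
        center = grid.center_key()
        coverage = np.full(16, 100)
        coverage[0] = 0  # starve the rightward bin
        rng = np.random.default_rng(3)
        k = plan_next_target(grid, center, 1, coverage, rng, scheme)
        ang = fb.selection_angle(center.center, k.center)
        assert fb.bin_of(ang, scheme) == 0

    def test_single_key_grid_errors(self, scheme):
        g1 = fb.GridSpec(rows=1, cols=1)
        with pytest.raises(ValueError):
            plan_next_target(g1, g1.key(0, 0), 1, np.zeros(16), np.random.default_rng(0), scheme)


class TestFitBin:
    def test_perfect_line(self):
        trials = [make_trial(x, 0.5 + 0.9 * x) for x in (1.0, 1.5, 2.0, 2.5, 3.0)]
        f = fit_bin(trials, SeedConfig())
        assert f.a_s == pytest.approx(0.5)
        assert f.b_s_per_bit == pytest.approx(0.9)
        assert f.r2 == pytest.approx(1.0)

    def test_constant_mt_degenerates(self):
        trials = [make_trial(x, 1.0) for x in (1.0, 2.0, 3.0)]
        f = fit_bin(trials, SeedConfig())
        assert f.b_s_per_bit == pytest.approx(0.0)
        assert f.r2 == 0.0

    def test_identical_ids_invalid(self):
        trials = [make_trial(2.0, mt) for mt in (0.8, 0.9, 1.0)]
        f = fit_bin(trials, SeedConfig())
        assert not f.valid
        assert f.r2 == 0.0

    def test_empty_bin(self):
        f = fit_bin([], SeedConfig(), bin_index=3)
        assert not f.valid
        assert f.n == 0
        assert math.isnan(f.a_s)

    def test_matches_normal_equation_oracle(self):
        # independent oracle: solve the 2x2 normal equations directly
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = rng.integers(5, 40)
            x = rng.uniform(0, 4, n)
            y = 0.7 + 0.5 * x + rng.normal(0, 0.2, n)
            lhs = np.array([[n, x.sum()], [x.sum(), (x**2).sum()]])
            a_ref, b_ref = np.linalg.solve(lhs, [y.sum(), (x * y).sum()])
            f = fit_bin([make_trial(xi, yi) for xi, yi in zip(x, y)], SeedConfig())
            assert f.a_s == pytest.approx(a_ref, rel=1e-9)
            assert f.b_s_per_bit == pytest.approx(b_ref, rel=1e-9)

    def test_noisy_recovery_close_to_truth(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 3.2, 25)
        y = 0.8 + 0.9 * x + rng.normal(0, 0.05, 25)
        f = fit_bin([make_trial(xi, yi) for xi, yi in zip(x, y)], SeedConfig())
        assert abs(f.a_s - 0.8) <= 0.1
        assert abs(f.b_s_per_bit - 0.9) <= 0.1


class TestOutliers:
    def _symmetric_sample(self, r):
        # 18 trials exactly on MT = 0.5 + 0.9 ID, plus two at the same ID
        # offset by +r and -r: the OLS line is unchanged and the residual SD
        # is exactly r/3, so the offset trials sit exactly at the 3-SD edge.
        xs = np.linspace(1.0, 3.0, 18)
        trials = [make_trial(x, 0.5 + 0.9 * x, trial_id=i) for i, x in enumerate(xs)]
        trials.append(make_trial(2.0, 0.5 + 0.9 * 2.0 + r, trial_id=18))
        trials.append(make_trial(2.0, 0.5 + 0.9 * 2.0 - r, trial_id=19))
        return trials

    def test_perfect_line_has_no_outliers(self):
        trials = [make_trial(x, 0.5 + 0.9 * x) for x in np.linspace(1, 3, 12)]
        f = fit_bin(trials, SeedConfig())
        assert detect_outliers(f, trials) == []

    def test_exactly_at_three_sd_not_flagged(self):
        # strict inequality at the band edge; 0.125 and its multiples are
        # exactly representable, so the comparison is exact
        f = FittsFit(0, 0.0, 0.0, 1.0, 20, 0.125, True)
        at_edge = make_trial(0.0, 0.375)
        just_over = make_trial(0.0, 0.3751)
        assert detect_outliers(f, [at_edge, just_over]) == [just_over]

    def test_inflated_trial_is_flagged(self):
        trials = self._symmetric_sample(0.3)
        bad = make_trial(1.5, 0.5 + 0.9 * 1.5 + 3.0, trial_id=20)  # ~10 sigma
        trials.append(bad)
        f = fit_bin(trials, SeedConfig())
        out = detect_outliers(f, trials)
        assert out == [bad]


class TestSampleConstants:
    def _profile(self, valid_bins, a=None, b=None):
        fits = []
        for k in range(16):
            ok = k in valid_bins
            fits.append(FittsFit(k, (a or {}).get(k, 0.5), (b or {}).get(k, 1.0),
                                 1.0 if ok else 0.0, 20 if ok else 0, 0.01, ok))
        return FittsProfile(scheme=fb.AngularBinScheme(), grid=fb.GridSpec(), fits=tuple(fits))

    def test_valid_bin_returns_its_constants(self):
        p = self._profile({2}, a={2: 0.7}, b={2: 1.2})
        assert sample_constants(p, 45.0) == (0.7, 1.2)  # 45 deg lies in bin 2
        # piecewise constant anywhere inside the bin
        assert sample_constants(p, 45.0) == sample_constants(p, 36.0)

    def test_equidistant_fallback_averages(self):
        p = self._profile({3, 5}, a={3: 0.4, 5: 0.8}, b={3: 1.0, 5: 2.0})
        a, b = sample_constants(p, 90.0)  # bin 4 invalid; 3 and 5 equidistant
        assert a == pytest.approx(0.6)
        assert b == pytest.approx(1.5)

    def test_no_valid_bins_raises(self):
        p = self._profile(set())
        with pytest.raises(ValueError):
            sample_constants(p, 0.0)


class TestRunCharacterization:
    def test_noiseless_user_terminates_after_seed_queue(self):
        user = fb.UserModel.isotropic(0.5, 1.0)
        profile, trials = run_characterization(user)
        assert len(trials) == 225
        assert all(f.valid and f.r2 == pytest.approx(1.0) for f in profile.fits)

    def test_noiseless_identifiability_per_bin(self):
        rng = np.random.default_rng(11)
        user = fb.UserModel.random_directional(rng, rng_seed=99)
        profile, _ = run_characterization(user, cfg=SeedConfig(rng_seed=4))
        for k, f in enumerate(profile.fits):
            assert abs(f.a_s - user.a_s[k]) <= 1e-6
            assert abs(f.b_s_per_bit - user.b_s_per_bit[k]) <= 1e-6

    def test_pure_noise_user_stops_exactly_at_cap(self):
        user = fb.UserModel(np.full(16, 0.5), np.zeros(16), noise_sd_s=0.5, rng_seed=3)
        _, trials = run_characterization(user)
        assert len(trials) == 400

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_target_conservation(self, seed):
        rng = np.random.default_rng(seed)
        user = fb.UserModel.random_directional(rng, noise_sd_s=0.2, rng_seed=seed)
        _, trials = run_characterization(user, cfg=SeedConfig(rng_seed=seed))
        assert 225 <= len(trials) <= 400
        assert [t.trial_id for t in trials] == list(range(len(trials)))

    def test_zero_distance_trials_have_no_bin(self):
        user = fb.UserModel.isotropic(0.5, 1.0)
        _, trials = run_characterization(user)
        zero = [t for t in trials if t.level == 0]
        assert len(zero) == 25
        for t in zero:
            assert t.distance_px == 0.0
            assert t.id_bits == 0.0
            assert t.bin == -1
            assert t.angle_deg is None
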