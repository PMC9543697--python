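"""Dose-ratio cost, side objective, pair bookkeeping and gradients."""

import numpy as np
import pytest

import filmcal as fc
from filmcal.objective import (
    AlignmentError,
    ConfigurationError,
    _core_cost,
    side_weight,
)


def make_measurement(k, level, od, r=None, plateau=None, ref=None):
    od = np.atleast_1d(np.asarray(od, dtype=float))
    r = np.full(od.shape, 20.0) if r is None else np.asarray(r, dtype=float)
    return fc.FilmMeasurement(
        k=k, level_id=level, gradient_r=r, gradient_od=od,
        plateau_od=plateau, reference_dose=ref,
        measurement_id=f"{level}_{k}_{id(od) % 997}",
    )


def synthetic_set(levels, reps=3, seed=0):
    noise = fc.NoiseSpec(0, 0, 0, seed=seed)
    return fc.simulate_measurement_set(levels=levels, reps=reps, noise=noise)


class TestEnumeratePairs:
    @pytest.mark.parametrize("n_levels, reps, expected", [(2, 3, 9), (4, 3, 54)])
    def test_pair_counts(self, n_levels, reps, expected):
        levels = [1.0 + i for i in range(n_levels)]
        ms = synthetic_set(levels, reps=reps)
        pairs = fc.enumerate_pairs(ms)
        assert len(pairs) == expected
        # brute-force oracle: all C(M,2) pairs minus same-level ones
        M = len(ms)
        brute = [
            (i, j)
            for i in range(M)
            for j in range(i + 1, M)
            if ms[i].level_id != ms[j].level_id
        ]
        assert pairs == brute

    def test_single_level_errors(self):
        ms = synthetic_set([2.0], reps=3)
        with pytest.raises(ConfigurationError):
            fc.enumerate_pairs(ms)

    def test_general_reps_formula(self):
        ms = synthetic_set([1.0, 2.0, 4.0], reps=2)
        assert len(fc.enumerate_pairs(ms)) == 2**2 * 3 * 2 // 2


class TestPairCost:
    def test_hand_computed_single_position(self, identity_cal):
        # Eq.: h^2 = (k_i k_j)^-2 (k_j d_i - k_i d_j)^2
        #          = (1*2)^-2 (2*1.0 - 1*1.5)^2 = 0.25 * 0.25 = 0.0625
        mi = make_measurement(1.0, "a", [1.0])
        mj = make_measurement(2.0, "b", [1.5])
        assert fc.pair_cost(mi, mj, identity_cal) == pytest.approx(0.0625)

    def test_symmetric_in_pair_order(self, identity_cal):
        mi = make_measurement(1.0, "a", [0.7, 0.9], r=[18, 22])
        mj = make_measurement(3.0, "b", [1.1, 1.4], r=[18, 22])
        assert fc.pair_cost(mi, mj, identity_cal) == pytest.approx(
            fc.pair_cost(mj, mi, identity_cal), rel=1e-14
        )

    def test_zero_at_generating_function(self, truth, clean_p1):
        mi = [m for m in clean_p1 if m.k == 1.0][0]
        mj = [m for m in clean_p1 if m.k == 5.0][0]
        assert fc.pair_cost(mi, mj, truth) == pytest.approx(0.0, abs=1e-18)

    def test_mismatched_grids_raise(self, identity_cal):
        mi = make_measurement(1.0, "a", [0.5, 0.6], r=[18, 20])
        mj = make_measurement(2.0, "b", [0.5, 0.6], r=[18, 21])
        with pytest.raises(AlignmentError):
            fc.pair_cost(mi, mj, identity_cal)


class TestCostRatio:
    def test_zero_at_truth_noise_free(self, truth, clean_p1):
        chi_a, n_pairs, nr = fc.cost_ratio(clean_p1, truth)
        assert chi_a <= 1e-20 * n_pairs * nr
        assert n_pairs == 9 * 12 * 11 // 2

    def test_scales_inverse_square_in_k(self, identity_cal):
        ms = [
            make_measurement(1.0, "a", [0.3, 0.5], r=[18, 22]),
            make_measurement(2.0, "b", [0.5, 0.8], r=[18, 22]),
            make_measurement(4.0, "c", [0.9, 1.2], r=[18, 22]),
        ]
        chi1, _, _ = fc.cost_ratio(ms, identity_cal)
        c = 2.0
        scaled = [
            make_measurement(m.k * c, m.level_id, m.gradient_od, r=m.gradient_r)
            for m in ms
        ]
        chi2, _, _ = fc.cost_ratio(scaled, identity_cal)
        assert chi2 == pytest.approx(chi1 / c**2, rel=1e-12)

    def test_permutation_invariance(self, truth, noisy_p1):
        rng = np.random.default_rng(5)
        cal = truth.with_range(1e-4, 1.0)
        sub = noisy_p1[:12]
        chi1, _, _ = fc.cost_ratio(sub, cal)
        perm = [sub[i] for i in rng.permutation(len(sub))]
        chi2, _, _ = fc.cost_ratio(perm, cal)
        assert chi2 == pytest.approx(chi1, rel=1e-12)


class TestCostSide:
    def test_zero_for_exact_calibration(self, identity_cal):
        ms = [
            make_measurement(1.0, "a", [0.5], plateau=1.0, ref=1.0),
            make_measurement(2.0, "b", [0.9], plateau=2.0, ref=2.0),
        ]
        assert fc.cost_side(ms, identity_cal) == pytest.approx(0.0, abs=1e-18)

    def test_weight_and_residual_formula(self, identity_cal):
        # one side point with residual 0.1 (normalized): chi_b = w_b * 0.01
        ms = [
            make_measurement(1.0, "a", [0.5], plateau=0.9, ref=1.0),
            make_measurement(2.0, "b", [0.9], plateau=2.1, ref=2.0),
        ]
        cfg = fc.ObjectiveConfig()
        w_b = side_weight(cfg, n_pairs=1, n_positions=1, n_d=1)
        assert w_b == pytest.approx(10.0)
        assert fc.cost_side(ms, identity_cal, cfg) == pytest.approx(
            w_b * 0.1**2, rel=1e-12
        )

    def test_highest_level_selection(self, identity_cal):
        # low-level reference errors must not contribute with default config
        ms = [
            make_measurement(1.0, "a", [0.5], plateau=123.0, ref=1.0),
            make_measurement(2.0, "b", [0.9], plateau=2.0, ref=2.0),
        ]
        assert fc.cost_side(ms, identity_cal) == pytest.approx(0.0, abs=1e-18)

    def test_missing_reference_errors(self, identity_cal):
        ms = [
            make_measurement(1.0, "a", [0.5]),
            make_measurement(2.0, "b", [0.9]),
        ]
        with pytest.raises(ConfigurationError):
            fc.cost_side(ms, identity_cal)

    def test_large_ws_forces_through_anchor(self, clean_p1):
        train = [m for m in clean_p1 if m.k in (0.75, 12.0)]
        cfg = fc.ObjectiveConfig(w_s=1e6)
        res = fc.fit_ratio_method(
            train, cfg, fc.FitConfig(family="polynomial", n_restarts=5, seed=2)
        )
        anchor = [m for m in train if m.k == 12.0]
        mean_od = np.mean([m.plateau_od for m in anchor])
        d = float(res.cal.inverse_dose(mean_od))
        assert abs(d - 12.0) / 12.0 < 1e-4


class TestTotalCostAndGradient:
    def test_chi_is_sum_of_parts(self, truth, noisy_p1):
        cal = truth.with_range(1e-4, 1.0)
        cb = fc.total_cost_and_gradient(noisy_p1, cal)
        chi_a, _, _ = fc.cost_ratio(noisy_p1, cal)
        chi_b = fc.cost_side(noisy_p1, cal)
        assert cb.chi == pytest.approx(cb.chi_a + cb.chi_b, rel=1e-14)
        assert cb.chi_a == pytest.approx(chi_a, rel=1e-12)
        assert cb.chi_b == pytest.approx(chi_b, rel=1e-12)

    def test_gradient_vanishes_at_noise_free_truth(self, truth, clean_p1):
        cb = fc.total_cost_and_gradient(clean_p1, truth)
        assert np.linalg.norm(cb.grad) < 1e-10

    @pytest.mark.parametrize("family", ["bimolecular", "polynomial"])
    def test_gradient_matches_finite_differences(self, family, noisy_p1):
        rng = np.random.default_rng(17)
        sub = noisy_p1[:9]
        h = 1e-7
        for _ in range(25):
            if family == "bimolecular":
                theta = np.array(
                    [rng.uniform(1.1, 1.6), rng.uniform(0.2, 2), rng.uniform(0.8, 1.4)]
                )
            else:
                theta = rng.normal(0, 0.3, 5)
            od_scale = max(
                float(np.max(np.concatenate([m.gradient_od for m in sub]))),
                max(m.plateau_od for m in sub),
            )
            cal = fc.CalibrationFunction(
                family, theta, od_scale=od_scale, dose_scale=12.0
            )
            cb = fc.total_cost_and_gradient(sub, cal)
            if cb.penalized:
                continue
            for m in range(len(theta)):
                tp, tm = theta.copy(), theta.copy()
                tp[m] += h
                tm[m] -= h
                cp = fc.total_cost_and_gradient(
                    sub, fc.CalibrationFunction(family, tp, od_scale, 12.0)
                )
                cm = fc.total_cost_and_gradient(
                    sub, fc.CalibrationFunction(family, tm, od_scale, 12.0)
                )
                fd = (cp.chi - cm.chi) / (2 * h)
                assert cb.grad[m] == pytest.approx(fd, rel=2e-5, abs=1e-6)

    def test_gradient_direction_invariant_under_k_scaling(self, identity_cal):
        ms = [
            make_measurement(1.0, "a", [0.3, 0.5], r=[18, 22], plateau=0.9, ref=1.0),
            make_measurement(2.0, "b", [0.5, 0.8], r=[18, 22], plateau=1.9, ref=2.0),
        ]
        cfg = fc.ObjectiveConfig(w_s=1e-12)  # isolate the chi_a part
        g1 = fc.total_cost_and_gradient(ms, identity_cal, cfg).grad
        scaled = [
            make_measurement(
                m.k * 3.0, m.level_id, m.gradient_od, r=m.gradient_r,
                plateau=m.plateau_od, ref=m.reference_dose * 3.0,
            )
            for m in ms
        ]
        g2 = fc.total_cost_and_gradient(scaled, identity_cal, cfg).grad
        np.testing.assert_allclose(g2, g1 / 9.0, rtol=1e-6)

    def test_penalty_for_infeasible_bimolecular(self, noisy_p1):
        cal = fc.CalibrationFunction("bimolecular", np.array([0.01, 1.0, 1.0]))
        cb = fc.total_cost_and_gradient(noisy_p1[:9], cal)
        assert cb.penalized
        assert np.isfinite(cb.chi) and cb.chi >= 1e10


class TestMeasurementValidation:
    def test_nonpositive_od_rejected(self):
        with pytest.raises(ValueError):
            make_measurement(1.0, "a", [0.5, -0.1], r=[18, 20])

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            make_measurement(0.0, "a", [0.5])
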