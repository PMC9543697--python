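"""Calibration-function families: evaluation, inversion, gradients."""

import json

import numpy as np
import pytest

from filmcal.models import (
    BijectivityError,
    CalibrationFunction,
    CalibrationRangeError,
)


def bimol(t1, t2, t3, **kw):
    return CalibrationFunction("bimolecular", np.array([t1, t2, t3]), **kw)


def poly(*theta, **kw):
    return CalibrationFunction("polynomial", np.array(theta, dtype=float), **kw)


class TestInverseDose:
    @pytest.mark.parametrize(
        "cal, o, expected",
        [
            (poly(0, 1, 0, 0, 0), 0.5, 0.5),           # identity polynomial
            (bimol(0.8, 3.0, 1.2), 0.4, 3.0),          # o = theta1/2 -> d = theta2
            (bimol(1.0, 1.0, 1.0), 0.25, 1.0 / 3.0),   # d = o/(1-o)
        ],
    )
    def test_known_values(self, cal, o, expected):
        assert cal.inverse_dose(o) == pytest.approx(expected, rel=1e-12)

    def test_bimolecular_matches_numerical_root_find(self):
        # independent check of d = o/(theta1-o): invert the forward map
        from scipy.optimize import brentq

        cal = bimol(1.0, 1.0, 1.0)
        o = 0.25
        d_root = brentq(
            lambda d: float(cal.forward_od(d)) - o, 1e-6, 50.0, xtol=1e-14
        )
        assert cal.inverse_dose(o) == pytest.approx(d_root, rel=1e-9)

    def test_vectorized(self):
        cal = poly(0, 2, 0)
        np.testing.assert_allclose(
            cal.inverse_dose([0.1, 0.2]), [0.2, 0.4], rtol=1e-14
        )

    def test_out_of_range_raises(self):
        cal = poly(0, 1, 0, valid_od_range=(0.1, 0.5))
        with pytest.raises(CalibrationRangeError):
            cal.inverse_dose(0.6)

    def test_bimolecular_domain_error(self):
        with pytest.raises(CalibrationRangeError):
            bimol(0.5, 1.0, 1.0).inverse_dose(0.6)


class TestForwardOd:
    @pytest.mark.parametrize(
        "cal, d, expected",
        [
            (bimol(1, 1, 1), 1.0, 0.5),
            (poly(0, 2, 0, 0, 0, valid_od_range=(0.01, 1.0)), 1.0, 0.5),
        ],
    )
    def test_known_values(self, cal, d, expected):
        assert float(cal.forward_od(d)) == pytest.approx(expected, rel=1e-10)

    def test_saturation_limits(self):
        cal = bimol(1, 1, 1)
        assert float(cal.forward_od(1e-9)) == pytest.approx(0.0, abs=1e-8)
        assert float(cal.forward_od(1e9)) == pytest.approx(1.0, abs=1e-8)

    def test_round_trip_bimolecular(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            t1 = rng.uniform(0.5, 1.5)
            t2 = rng.uniform(1.0, 8.0)
            t3 = rng.uniform(0.8, 1.5)
            cal = bimol(t1, t2, t3)
            d = rng.uniform(0.1, 15.0, 50)
            d_back = cal.inverse_dose(cal.forward_od(d))
            np.testing.assert_allclose(d_back, d, rtol=1e-9)

    def test_polynomial_round_trip(self):
        cal = poly(0.05, 2.0, 1.0, valid_od_range=(0.01, 1.0))
        d = np.linspace(*sorted([float(cal.inverse_dose(0.02)),
                                 float(cal.inverse_dose(0.9))]), 17)
        np.testing.assert_allclose(
            cal.inverse_dose(cal.forward_od(d)), d, rtol=1e-9
        )

    def test_non_monotone_polynomial_raises(self):
        cal = poly(0, 1, 0, 0, -5, valid_od_range=(0.01, 1.0))
        with pytest.raises(BijectivityError):
            cal.forward_od(0.2)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            bimol(1, 1, 1).forward_od(0.0)


class TestParameterGradient:
    def test_polynomial_powers(self):
        g = poly(0, 1, 0, 0, 0).parameter_gradient(0.5)
        np.testing.assert_allclose(g, [1, 0.5, 0.25, 0.125, 0.0625], rtol=1e-14)

    def test_bimolecular_theta2_component_is_d_over_theta2(self):
        cal = bimol(1.0, 2.0, 1.3)
        o = 0.37
        g = cal.parameter_gradient(o)
        assert g[1] == pytest.approx(float(cal.inverse_dose(o)) / 2.0, rel=1e-12)

    @pytest.mark.parametrize("family", ["bimolecular", "polynomial"])
    def test_matches_central_differences(self, family):
        rng = np.random.default_rng(3)
        h = 1e-6
        for _ in range(100):
            if family == "bimolecular":
                theta = np.array(
                    [rng.uniform(0.6, 1.4), rng.uniform(0.5, 5), rng.uniform(0.8, 1.5)]
                )
                o = rng.uniform(0.05, 0.9) * theta[0]
            else:
                theta = rng.normal(0, 1, 5)
                o = rng.uniform(0.05, 1.0)
            cal = CalibrationFunction(family, theta)
            g = cal.parameter_gradient(o)
            for m in range(len(theta)):
                tp, tm = theta.copy(), theta.copy()
                tp[m] += h
                tm[m] -= h
                fd = (
                    CalibrationFunction(family, tp).inverse_dose(o)
                    - CalibrationFunction(family, tm).inverse_dose(o)
                ) / (2 * h)
                assert g[m] == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestBijectivityCheck:
    @pytest.mark.parametrize(
        "theta, ok",
        [
            ((0, 1, 0, 0, 0), True),
            ((0, -1, 0, 0, 0), False),   # decreasing
            ((0, 1, 0, 0, -5), False),   # turns over at o = (1/20)**(1/3)
        ],
    )
    def test_polynomial_cases(self, theta, ok):
        cal = poly(*theta, valid_od_range=(0.01, 1.0))
        result, why = cal.check_bijective()
        assert result is ok

    def test_turnover_location_reported(self):
        cal = poly(0, 1, 0, 0, -5, valid_od_range=(0.01, 1.0))
        _, why = cal.check_bijective(n_grid=4096)
        # derivative 1 - 20 o^3 = 0 at o ~ 0.368
        assert "0.36" in why or "0.37" in why


class TestNormalization:
    def test_polynomial_denormalization_identity(self):
        rng = np.random.default_rng(11)
        theta_n = rng.normal(0, 0.5, 5)
        od_scale, dose_scale = 0.47, 12.0
        cal = CalibrationFunction("polynomial", theta_n, od_scale, dose_scale)
        o = rng.uniform(0.01, od_scale, 40)
        d_norm_path = cal.inverse_dose(o)
        theta_phys = cal.theta_physical
        d_phys_path = np.polyval(theta_phys[::-1], o)
        np.testing.assert_allclose(d_norm_path, d_phys_path, rtol=1e-12)

    def test_physical_round_trip_both_families(self):
        for family, theta in [
            ("polynomial", np.array([0.1, 2.0, -0.5, 0.2, 0.05])),
            ("bimolecular", np.array([1.1, 0.4, 1.2])),
        ]:
            cal = CalibrationFunction(family, theta, od_scale=0.5, dose_scale=10.0)
            cal2 = CalibrationFunction.from_physical(
                family, cal.theta_physical, od_scale=0.5, dose_scale=10.0
            )
            np.testing.assert_allclose(cal2.theta, theta, rtol=1e-12)


class TestPropertyBased:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        t1=st.floats(0.5, 1.5),
        t2=st.floats(0.5, 8.0),
        t3=st.floats(0.8, 1.5),
        d=st.floats(0.1, 15.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_bimolecular_round_trip_identity(self, t1, t2, t3, d):
        cal = bimol(t1, t2, t3)
        assert float(cal.inverse_dose(cal.forward_od(d))) == pytest.approx(
            d, rel=1e-9
        )

    @given(
        scale_o=st.floats(0.1, 2.0),
        scale_d=st.floats(0.5, 20.0),
        o=st.floats(0.02, 0.95),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_normalized_and_physical_evaluation_agree(self, scale_o, scale_d, o):
        theta_n = np.array([0.1, 1.5, -0.4, 0.3, 0.05])
        cal = CalibrationFunction("polynomial", theta_n, scale_o, scale_d)
        d1 = float(cal.inverse_dose(o * scale_o))
        d2 = float(np.polyval(cal.theta_physical[::-1], o * scale_o))
        assert d1 == pytest.approx(d2, rel=1e-10, abs=1e-12)


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        cal = CalibrationFunction(
            "bimolecular",
            np.array([1.2, 0.5, 1.1]),
            od_scale=0.6,
            dose_scale=12.0,
            valid_od_range=(0.01, 0.58),
            meta={"method": "ratio"},
        )
        path = tmp_path / "cal.json"
        cal.to_json(path)
        back = CalibrationFunction.from_json(path)
        np.testing.assert_allclose(back.theta, cal.theta, rtol=1e-12)
        assert back.valid_od_range == cal.valid_od_range
        assert back.family == cal.family
        o = np.linspace(0.02, 0.5, 11)
        np.testing.assert_allclose(
            back.inverse_dose(o), cal.inverse_dose(o), rtol=1e-12
        )

    def test_json_document_fields(self):
        cal = CalibrationFunction("polynomial", np.zeros(5) + 0.1)
        doc = json.loads(cal.to_json())
        assert doc["family"] == "polynomial"
        assert doc["degree"] == 4
        assert len(doc["theta"]) == 5


class TestValidation:
    def test_bad_family(self):
        with pytest.raises(ValueError):
            CalibrationFunction("rational", np.array([1.0]))

    def test_bimolecular_needs_three_params(self):
        with pytest.raises(ValueError):
            CalibrationFunction("bimolecular", np.array([1.0, 2.0]))

    def test_bad_range(self):
        with pytest.raises(ValueError):
            poly(0, 1, valid_od_range=(0.5, 0.1))
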