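"""Pristine-Bragg IDD model, cross-section correction, absolute scaling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import carbonpbs as c
from carbonpbs.depthdose import DepthDoseSet, default_sigma_strag


@pytest.fixture
def params():
    return c.PristineBeamParams(R0=150.0, lam=150.0, lam_prime=150.0,
                                sigma_strag=1.5)


class TestFluence:
    def test_half_value_thickness(self, params):
        assert c.fluence(0.0, params) == pytest.approx(1.0)
        assert c.fluence(params.lam, params) == pytest.approx(0.5)
        assert c.fluence(2 * params.lam, params) == pytest.approx(0.25)


class TestPristineIdd:
    def test_delta_function_limit(self, stopping):
        """With vanishing straggling the curve tends to Phi(z) S(R0 - z)."""
        p = c.PristineBeamParams(R0=150.0, lam=150.0, lam_prime=150.0,
                                 sigma_strag=1e-3)
        z = np.array([20.0, 80.0, 120.0])
        got = c.pristine_idd(z, p, stopping)
        want = c.fluence(z, p) * stopping.s_of_r(p.R0 - z)
        assert got == pytest.approx(want, rel=1e-3)

    def test_peak_position_near_r0(self, stopping, params):
        z = np.arange(140.0, 155.0, 0.05)
        curve = c.pristine_idd(z, params, stopping)
        zpk = z[np.argmax(curve)]
        assert abs(zpk - params.R0) < params.sigma_strag

    def test_beyond_range_is_zero(self, stopping, params):
        z = params.R0 + 5 * params.sigma_strag + 1.0
        assert c.pristine_idd(z, params, stopping)[0] == 0.0

    def test_convolution_preserves_integral_for_symmetric_s(self):
        """Against a brute-force fine-grid quadrature with a smooth S."""
        r = np.linspace(0.0, 400.0, 4001)
        sp = c.StoppingPowerCurve(r_grid=r[1:], s_r=2.0 + 0.01 * r[1:],
                                  e_grid=[1, 500], s_e=[1, 1])
        p = c.PristineBeamParams(R0=200.0, lam=1e9, lam_prime=1e9,
                                 sigma_strag=2.0)
        z = np.arange(20.0, 180.0, 0.25)
        conv = c.pristine_idd(z, p, sp)
        direct = sp.s_of_r(p.R0 - z)
        # away from the endpoint the Gaussian smoothing of a linear S is exact
        assert np.trapezoid(conv, z) == pytest.approx(
            np.trapezoid(direct, z), rel=1e-3)

    def test_lambda_rescaling_scales_by_fluence_factor(self, stopping):
        """Quadrature oracle: the lambda dependence is exactly the fluence."""
        z = np.arange(0.0, 160.0, 0.5)
        p1 = c.PristineBeamParams(R0=150.0, lam=150.0, lam_prime=150.0,
                                  sigma_strag=1.5)
        p2 = c.PristineBeamParams(R0=150.0, lam=120.0, lam_prime=120.0,
                                  sigma_strag=1.5)
        c1 = c.pristine_idd(z, p1, stopping)
        c2 = c.pristine_idd(z, p2, stopping)
        ratio = np.power(2.0, z / 150.0 - z / 120.0)
        np.testing.assert_allclose(c2, c1 * ratio, rtol=1e-12)


class TestCrossSectionCorrection:
    def test_identity_cases(self):
        z = np.arange(0.0, 300.0, 10.0)
        idd = np.exp(-z / 100.0)
        np.testing.assert_allclose(c.correct_idd_12c(idd, z, 170.0, 170.0), idd)
        assert c.correct_idd_12c(idd, np.zeros_like(z), 170.0, 150.0)[0] \
            == pytest.approx(idd[0])

    def test_printed_lambda_values(self):
        # lambda = 170 mm before, 150 mm after correction; z = 300 mm
        factor = c.correct_idd_12c(np.array([1.0]), np.array([300.0]),
                                   170.0, 150.0)[0]
        assert factor == pytest.approx(2.0 ** (300 / 170 - 300 / 150), rel=1e-12)
        assert factor == pytest.approx(0.8494, abs=5e-4)

    def test_fragment_factor_is_depth_independent(self):
        idd = np.array([1.0, 2.0, 5.0])
        out = c.correct_idd_frag(idd, 170.0, 150.0)
        np.testing.assert_allclose(out / idd, 170.0 / 150.0)

    @settings(derandomize=True, max_examples=25)
    @given(l1=st.floats(80.0, 300.0), l2=st.floats(80.0, 300.0),
           l3=st.floats(80.0, 300.0))
    def test_correction_composes_and_inverts(self, l1, l2, l3):
        z = np.arange(0.0, 350.0, 25.0)
        idd = np.exp(-z / 200.0)
        back = c.correct_idd_12c(c.correct_idd_12c(idd, z, l1, l2), z, l2, l1)
        np.testing.assert_allclose(back, idd, rtol=1e-10)
        direct = c.correct_idd_12c(idd, z, l1, l3)
        chained = c.correct_idd_12c(c.correct_idd_12c(idd, z, l1, l2), z, l2, l3)
        np.testing.assert_allclose(chained, direct, rtol=1e-10)


class TestDap:
    def test_arithmetic(self):
        dap = c.dap_from_grid(c.DapCalibration(d_meas=0.9, spacing_delta=3.0,
                                               q_per_spot=0.05))
        assert dap == pytest.approx(162.0)

    def test_scaling_laws(self):
        base = c.DapCalibration(d_meas=0.9, spacing_delta=3.0, q_per_spot=0.05)
        assert c.dap_from_grid(
            c.DapCalibration(0.9, 3.0, 0.1)) == pytest.approx(
                c.dap_from_grid(base) / 2)
        assert c.dap_from_grid(
            c.DapCalibration(0.9, 6.0, 0.05)) == pytest.approx(
                4 * c.dap_from_grid(base))


class TestToAbsolute:
    def make_dds(self):
        z = np.arange(0.0, 100.0, 0.5)
        idd1 = 10.0 + z / 10.0
        frag = 1.0 + z / 50.0
        return DepthDoseSet(z=z, idd1=idd1, idd_frag=frag, absolute=False)

    def test_pins_total_at_calibration_depth(self):
        dds = self.make_dds()
        out = c.to_absolute(dds, dap_2cm=162.0)
        assert float(out.interp("idd_total", 20.0)) == pytest.approx(162.0)
        assert out.absolute

    def test_preserves_ratios_and_roundtrips(self):
        dds = self.make_dds()
        out = c.to_absolute(dds, dap_2cm=162.0)
        np.testing.assert_allclose(out.idd1 / out.idd_total,
                                   dds.idd1 / dds.idd_total, rtol=1e-12)
        back = c.to_absolute(out, float(dds.interp("idd_total", 20.0)))
        np.testing.assert_allclose(back.idd1, dds.idd1, rtol=1e-12)

    def test_identity_when_already_calibrated(self):
        dds = self.make_dds()
        same = c.to_absolute(dds, float(dds.interp("idd_total", 20.0)))
        np.testing.assert_allclose(same.idd1, dds.idd1, rtol=1e-12)

    def test_zero_total_raises(self):
        z = np.arange(0.0, 100.0, 0.5)
        dds = DepthDoseSet(z=z, idd1=np.zeros_like(z),
                           idd_frag=np.zeros_like(z))
        with pytest.raises(c.DegenerateInputError):
            c.to_absolute(dds, 162.0)


class TestDetectionEfficiency:
    def test_chamber_value(self):
        assert c.detection_efficiency(60.0, 25.0) == pytest.approx(0.9439, abs=1e-4)

    def test_limits(self):
        assert c.detection_efficiency(1e6, 25.0) == pytest.approx(1.0)
        half_mass = 25.0 * np.sqrt(2 * np.log(2))
        assert c.detection_efficiency(half_mass, 25.0) == pytest.approx(0.5)

    def test_matches_polar_quadrature(self):
        """Independent check by numerical integration of the 2-D Gaussian."""
        from scipy.integrate import quad
        sigma = 25.0
        R = 60.0
        val, _ = quad(lambda r: r * np.exp(-r ** 2 / (2 * sigma ** 2))
                      / sigma ** 2, 0.0, R)
        assert c.detection_efficiency(R, sigma) == pytest.approx(val, rel=1e-9)


class TestDecomposeFragment:
    def test_algebraic_inverse(self):
        z = np.arange(5)
        frag = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        idd3 = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        idd2 = c.decompose_fragment(frag, idd3, 0.9)
        np.testing.assert_allclose(idd2 + 0.9 * idd3, frag)

    def test_limiting_cases(self):
        frag = np.array([1.0, 2.0])
        assert c.decompose_fragment(frag, frag, 1.0) == pytest.approx([0.0, 0.0])
        np.testing.assert_allclose(
            c.decompose_fragment(frag, np.zeros(2), 0.5), frag)

    def test_clamps_at_zero(self):
        out = c.decompose_fragment(np.array([1.0]), np.array([10.0]), 1.0)
        assert out[0] == 0.0

    def test_rejects_bad_epsilon(self):
        with pytest.raises(c.InvalidParameterError):
            c.decompose_fragment(np.ones(2), np.ones(2), 1.5)


def test_default_sigma_strag_scaling():
    assert default_sigma_strag(300.0) == pytest.approx(0.012 * 300 ** 0.935)
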