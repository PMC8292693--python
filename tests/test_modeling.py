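"""Frame patterns, fragment-parameter extraction, IDNF, and LQ fits."""

import numpy as np
import pytest

import carbonpbs as c
from carbonpbs import modeling
from carbonpbs.engine import Spot, SpotList
from conftest import frame_measurement_set


class TestFramePattern:
    @pytest.mark.parametrize("pid,inner,outer,count", [
        ("A", 0, 12, 81), ("B", 12, 18, 120), ("C", 18, 24, 168),
        ("D", 24, 30, 216), ("E", 30, 36, 264), ("F", 36, 42, 312),
        ("G", 42, 48, 360),
    ])
    def test_standard_pattern_counts(self, pid, inner, outer, count):
        pat = c.generate_frame_pattern(inner, outer, 3.0)
        assert pat.count == count

    def test_single_spot_and_brute_force_count(self):
        assert c.generate_frame_pattern(0, 0, 3.0).count == 1
        # brute-force oracle: enumerate the lattice and filter
        pat = c.generate_frame_pattern(9, 21, 3.0)
        brute = sum(1 for x in range(-21, 22, 3) for y in range(-21, 22, 3)
                    if 9 <= max(abs(x), abs(y)) <= 21)
        assert pat.count == brute

    def test_rejects_non_multiple_bounds(self):
        with pytest.raises(c.InvalidParameterError):
            c.generate_frame_pattern(10, 21, 3.0)


class TestFrameCenterDose:
    def test_matches_brute_force_spot_sum(self, library):
        beam = library.beam_for_range(150.0)
        pat = c.generate_frame_pattern(12, 18, 3.0)
        z, w = 100.0, 0.02
        got = c.frame_center_dose(pat, beam, z, w)
        s1x, s1y, s2, s3 = (float(v[0]) for v in beam.sigmas(np.array([z])))
        brute = 0.0
        for x, y in pat.spots:
            brute += w * (
                float(beam.dds.interp("idd1", z))
                * c.lateral_gaussian((0, 0), (x, y), 1, (s1x, s1y))
                + float(beam.dds.interp("idd2", z))
                * c.lateral_gaussian((0, 0), (x, y), 2, s2)
                + float(beam.dds.interp("idd3", z))
                * c.lateral_gaussian((0, 0), (x, y), 3, s3))
        assert got == pytest.approx(brute, rel=1e-9)

    def test_linear_in_weight(self, library):
        beam = library.beam_for_range(120.0)
        pat = c.generate_frame_pattern(36, 42, 3.0)
        d1 = c.frame_center_dose(pat, beam, 60.0, 0.01)
        assert c.frame_center_dose(pat, beam, 60.0, 0.03) == pytest.approx(
            3 * d1, rel=1e-12)

    def test_distant_frame_sees_no_primary(self, library):
        """With the halo removed, a frame at >= 8 sigma1 deposits ~nothing."""
        beam = library.beam_for_range(150.0)
        pat = c.generate_frame_pattern(42, 48, 3.0)
        z = 50.0
        xs, ys = pat.spots[:, 0], pat.spots[:, 1]
        from carbonpbs.engine import dose_components_at_points
        d1, _, _ = dose_components_at_points(
            beam, xs, ys, np.full(pat.count, 1.0), [0.0], [0.0], [z])
        on_axis = float(beam.dds.interp("idd1", z)) / (
            2 * np.pi * float(beam.sigmas(np.array([z]))[0][0]) ** 2)
        assert float(d1[0]) < 1e-6 * on_axis


class TestFragmentFit:
    def test_noiseless_roundtrip(self, small_ladder):
        lib, _ = small_ladder
        bid = max(lib.beams, key=lambda b: lib.beams[b].water_range)
        beam = lib.beams[bid]
        ms = frame_measurement_set(lib, [bid])
        fits = c.fit_fragment_components(ms, beam, seed=0)
        assert len(fits) == 7
        for f in fits:
            want2 = float(beam.dds.interp("idd2", f.depth))
            want3 = float(beam.dds.interp("idd3", f.depth))
            wants2 = float(beam.sigmas(np.array([f.depth]))[2][0])
            assert f.idd2 == pytest.approx(want2, rel=0.02, abs=1e-3)
            assert f.idd3 == pytest.approx(want3, rel=0.02, abs=1e-3)
            assert f.sigma2 == pytest.approx(wants2, rel=0.05)
            assert f.sigma3 == 25.0  # constrained second pass

    def test_noisy_roundtrip_within_ten_percent(self, small_ladder):
        lib, _ = small_ladder
        bid = max(lib.beams, key=lambda b: lib.beams[b].water_range)
        beam = lib.beams[bid]
        rng = np.random.default_rng(11)
        ms = [modeling.FrameMeasurement(
                  m.beam_id, m.pattern_id, m.depth,
                  m.dose * (1.0 + 0.01 * rng.standard_normal()),
                  m.w_per_spot)
              for m in frame_measurement_set(lib, [bid])]
        fits = c.fit_fragment_components(ms, beam, seed=0)
        for f in fits:
            want2 = float(beam.dds.interp("idd2", f.depth))
            assert f.idd2 == pytest.approx(want2, rel=0.10, abs=0.05)

    def test_requires_four_patterns(self, small_ladder):
        lib, _ = small_ladder
        bid = sorted(lib.beams)[0]
        ms = frame_measurement_set(lib, [bid])[:3]
        with pytest.raises(c.InvalidParameterError):
            c.fit_fragment_components(ms, lib.beams[bid], seed=0)


class TestHaloModelFits:
    def test_sigma2_constant_recovery(self):
        zp = 200.0
        z = np.array([40.0, 80.0, 120.0, 160.0, 185.0, 210.0, 230.0])
        m = c.FragmentSigmaModel(zp=zp)
        vals = c.sigma2(z, m)
        fit = c.fit_sigma2_function(z, vals, zp, seed=0)
        assert fit.c1 == pytest.approx(5.0, rel=0.05)
        assert fit.c2 == pytest.approx(30.0, rel=0.05)
        assert fit.c3 == pytest.approx(0.006, rel=0.05)

    def test_sigma2_constant_data_gives_tiny_c3(self):
        z = np.linspace(20, 230, 8)
        fit = c.fit_sigma2_function(z, np.full_like(z, 5.0), 200.0, seed=0)
        assert fit.c3 == pytest.approx(0.0, abs=1e-4)

    def test_idd3_constant_recovery(self):
        zp = 200.0
        z = np.array([20.0, 60.0, 100.0, 150.0, 190.0, 220.0, 260.0])
        m = c.FragmentIddModel(zp=zp)
        vals = c.idd3(z, m)
        fit = c.fit_idd3_function(z, vals, zp, seed=0)
        assert fit.c4 == pytest.approx(21.0, rel=0.05)
        assert fit.c5 == pytest.approx(500.0, rel=0.05)
        assert fit.c6 == pytest.approx(1.5, rel=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(c.InvalidParameterError):
            c.fit_sigma2_function([1, 2, 3], [5, 5, 5], 200.0)


class TestIdnf:
    def _case(self, library, factor=1.0):
        beam = library.beam_for_range(120.0)
        spots = [Spot(float(x), float(y), beam.beam_id, 0.05)
                 for x in np.arange(-30, 31, 3.0)
                 for y in np.arange(-30, 31, 3.0)]
        sl = SpotList(spots)
        from carbonpbs.engine import dose_components_at_points
        xs, ys, ws = sl.by_beam()[beam.beam_id]
        d1, d2, d3 = dose_components_at_points(
            beam, xs, ys, ws, [0.0], [0.0], [80.0])
        dose = float(d1[0] + d2[0] + d3[0])
        return modeling.IdnfCase("c", sl, (0.0, 0.0, 80.0), dose * factor), beam

    def test_self_consistent_measurements_give_unit_factors(self, library):
        case, beam = self._case(library)
        table = c.compute_idnf([case], library)
        assert table.factors[beam.beam_id] == pytest.approx(1.0, abs=1e-6)

    def test_global_scale_recovered(self, library):
        case, beam = self._case(library, factor=1.02)
        table = c.compute_idnf([case], library)
        assert table.factors[beam.beam_id] == pytest.approx(1.02, abs=1e-4)

    def test_single_beam_single_case_exact_ratio(self, library):
        case, beam = self._case(library, factor=0.97)
        table = c.compute_idnf([case], library)
        assert table.factors[beam.beam_id] == pytest.approx(0.97, abs=1e-6)

    def test_applying_factors_reduces_residuals(self, library):
        case, beam = self._case(library, factor=1.02)
        table = c.compute_idnf([case], library)
        corrected = table.apply(library)
        from carbonpbs.engine import dose_components_at_points
        xs, ys, ws = case.spot_list.by_beam()[beam.beam_id]
        d1, d2, d3 = dose_components_at_points(
            corrected.beams[beam.beam_id], xs, ys, ws, [0.0], [0.0], [80.0])
        assert float(d1[0] + d2[0] + d3[0]) == pytest.approx(
            case.measured_dose, rel=1e-4)

    def test_factor_bounds_enforced(self):
        with pytest.raises(c.InvalidParameterError):
            modeling.IdnfTable({"b": 1.5})


class TestLqSurvivalFit:
    def test_exact_recovery_of_printed_constants(self):
        d = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        sf = np.exp(-(0.77 * d + 0.074 * d ** 2))
        alpha, beta = c.fit_lq_survival(list(zip(d, sf)))
        assert alpha == pytest.approx(0.77, abs=1e-6)
        assert beta == pytest.approx(0.074, abs=1e-6)

    def test_pure_alpha_curve_gives_zero_beta(self):
        d = np.array([1.0, 2.0, 4.0])
        sf = np.exp(-0.5 * d)
        alpha, beta = c.fit_lq_survival(list(zip(d, sf)))
        assert alpha == pytest.approx(0.5, abs=1e-9)
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_no_intercept_by_construction(self):
        # the fitted model predicts SF(0) = 1 exactly
        d = np.array([1.0, 2.0, 3.0])
        sf = np.exp(-(0.4 * d + 0.02 * d ** 2)) * [1.02, 0.98, 1.01]
        alpha, beta = c.fit_lq_survival(list(zip(d, sf)))
        assert np.exp(-(alpha * 0 + beta * 0)) == 1.0

    def test_degenerate_single_dose_level(self):
        with pytest.raises(c.FitFailureError):
            c.fit_lq_survival([(2.0, 0.5), (2.0, 0.45), (2.0, 0.55)])


class TestLambdaCorrection:
    def test_recovers_truth_attenuation_length(self, small_ladder):
        lib, mset = small_ladder
        bid = sorted(mset.beams)[0]
        bm = mset.beams[bid]
        lam = modeling.fit_lambda_correction(
            bm.z, bm.raw_idd_12c, bm.raw_idd_frag, bm.chamber_idd,
            mset.lam_raw)
        assert lam == pytest.approx(mset.truth.lam_true, rel=0.02)
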