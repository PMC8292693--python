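"""Triple-Gaussian superposition, beam splitting, and WEPL."""

import math

import numpy as np
import pytest

import carbonpbs as c
from carbonpbs.engine import (DoseGrid, Spot, SpotList,
                              dose_components_at_points,
                              first_component_profile_split, pencil_dose,
                              split_beam, total_dose, wepl_along_axis)


@pytest.fixture(scope="module")
def beam(library):
    return library.beam_for_range(150.0)


class TestLateralGaussian:
    def test_center_values(self):
        v = c.lateral_gaussian((0, 0), (0, 0), 1, (3.0, 4.0))
        assert v == pytest.approx(1.0 / (2 * math.pi * 12.0))
        v2 = c.lateral_gaussian((0, 0), (0, 0), 2, 5.0)
        assert v2 == pytest.approx(1.0 / (2 * math.pi * 25.0))

    def test_plane_integral_is_unity(self):
        """2-D quadrature oracle on a fine grid."""
        x = np.linspace(-20, 20, 401)
        X, Y = np.meshgrid(x, x)
        vals = np.array([[c.lateral_gaussian((xx, yy), (0, 0), 1, (2.0, 3.0))
                          for xx in x[::8]] for yy in x[::8]])
        # integrate on the decimated grid (step 0.8 mm)
        integral = vals.sum() * 0.8 ** 2
        assert integral == pytest.approx(1.0, abs=1e-4)

    def test_isotropy_of_halo_component(self):
        r = 7.0
        a = c.lateral_gaussian((r, 0), (0, 0), 2, 5.0)
        b = c.lateral_gaussian((r / math.sqrt(2), r / math.sqrt(2)), (0, 0),
                               2, 5.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(c.InvalidParameterError):
            c.lateral_gaussian((0, 0), (0, 0), 2, 0.0)


class TestPencilDose:
    def test_zero_weight_and_linearity(self, beam):
        p = (2.0, -1.0, 100.0)
        assert pencil_dose(p, beam, 0.0) == 0.0
        d1 = pencil_dose(p, beam, 1.0)
        assert pencil_dose(p, beam, 3.5) == pytest.approx(3.5 * d1, rel=1e-12)

    def test_on_axis_closed_form_assembly(self, beam):
        z = 100.0
        s1x, s1y, s2, s3 = (float(v[0]) for v in beam.sigmas(np.array([z])))
        want = (beam.dds.interp("idd1", z) / (2 * math.pi * s1x * s1y)
                + beam.dds.interp("idd2", z) / (2 * math.pi * s2 ** 2)
                + beam.dds.interp("idd3", z) / (2 * math.pi * s3 ** 2))
        assert pencil_dose((0, 0, z), beam, 1.0) == pytest.approx(
            float(want), rel=1e-12)

    def test_outside_depth_range_is_zero(self, beam):
        assert pencil_dose((0, 0, 400.0), beam, 1.0) == 0.0

    def test_plane_integral_equals_idd_sum(self, beam):
        """Dose conservation: lateral quadrature returns w * sum IDD_n."""
        z = 120.0
        x = np.arange(-120.0, 120.0, 1.0)
        X, Y = np.meshgrid(x, x)
        d1, d2, d3 = dose_components_at_points(
            beam, [0.0], [0.0], [1.0], X.ravel(), Y.ravel(),
            np.full(X.size, z))
        integral = (d1 + d2 + d3).sum() * 1.0
        want = float(beam.dds.interp("idd1", z) + beam.dds.interp("idd2", z)
                     + beam.dds.interp("idd3", z))
        assert integral == pytest.approx(want, rel=5e-3)


class TestTotalDose:
    def grid(self):
        return DoseGrid(origin=(-20.0, -20.0, 10.0), spacing=(2.0, 2.0, 20.0),
                        dims=(21, 21, 7))

    def test_single_spot_matches_pencil(self, library, beam):
        sl = SpotList([Spot(1.0, -2.0, beam.beam_id, 0.7)])
        out = total_dose(self.grid(), sl, library.beams)
        gx, gy, gz = (out.axis(i) for i in range(3))
        for ix, iz in ((10, 2), (13, 4), (5, 6)):
            want = pencil_dose((gx[ix], gy[10], gz[iz]), beam, 0.7,
                               center=(1.0, -2.0))
            assert out.data[ix, 10, iz] == pytest.approx(want, rel=1e-6,
                                                         abs=1e-12)

    def test_spot_order_invariance(self, library, beam):
        spots = [Spot(float(x), float(y), beam.beam_id, 0.1)
                 for x in (-3, 0, 3) for y in (-3, 0, 3)]
        a = total_dose(self.grid(), SpotList(spots), library.beams)
        b = total_dose(self.grid(), SpotList(spots[::-1]), library.beams)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_translation_invariance(self, library, beam):
        sl = SpotList([Spot(0.0, 0.0, beam.beam_id, 1.0),
                       Spot(3.0, 3.0, beam.beam_id, 0.5)])
        shift = np.array([8.0, -6.0, 0.0])
        g1 = self.grid()
        g2 = DoseGrid(origin=g1.origin + shift, spacing=g1.spacing,
                      dims=g1.dims)
        moved = SpotList([Spot(s.x + shift[0], s.y + shift[1], s.beam_id, s.w)
                          for s in sl.spots])
        a = total_dose(g1, sl, library.beams)
        b = total_dose(g2, moved, library.beams)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_uniform_lattice_matches_idd_over_spacing_squared(self, library,
                                                              beam):
        """Lattice-sum oracle: central-axis dose = Q * sum IDD_n / spacing^2."""
        Q, delta = 0.05, 3.0
        pad = 150.0  # >= 10 sigma for components 1-2, 6 sigma for the third
        xs = np.arange(-pad, pad + 1e-9, delta)
        spots = [Spot(float(x), float(y), beam.beam_id, Q)
                 for x in xs for y in xs]
        grid = DoseGrid(origin=(0.0, 0.0, 20.0), spacing=(1.0, 1.0, 40.0),
                        dims=(1, 1, 4))
        out = total_dose(grid, SpotList(spots), library.beams)
        z = grid.axis(2)
        want = Q * (beam.dds.interp("idd1", z) + beam.dds.interp("idd2", z)
                    + beam.dds.interp("idd3", z)) / delta ** 2
        np.testing.assert_allclose(out.data[0, 0, :], want, rtol=2e-3)

    def test_unknown_beam_id_raises(self, library):
        sl = SpotList([Spot(0.0, 0.0, "nope", 1.0)])
        with pytest.raises(c.InvalidParameterError):
            total_dose(self.grid(), sl, library.beams)


class TestSplitBeam:
    def test_weights_sum_to_one_and_fixed_count(self, beam):
        ss = split_beam(beam)
        assert len(ss.weights) == 19
        assert ss.weights.sum() == pytest.approx(1.0, rel=1e-9)
        # count is a fixed policy, independent of geometry
        assert len(split_beam(beam, density_grid="ignored").weights) == 19

    def test_recombination_matches_unsplit_in_water(self, beam):
        """Recombined first component within 1% wherever dose > 10% of max."""
        ss = split_beam(beam)
        x = np.linspace(-12.0, 12.0, 49)
        for z in (20.0, 80.0, 145.0):
            s1x, s1y, _, _ = beam.sigmas(np.array([z]))
            exact = (np.exp(-x ** 2 / (2 * float(s1x[0]) ** 2))
                     / (2 * np.pi * float(s1x[0]) * float(s1y[0])))
            approx = first_component_profile_split(beam, ss, x,
                                                   np.zeros_like(x), z)
            m = exact > 0.1 * exact.max()
            assert np.max(np.abs(approx[m] / exact[m] - 1.0)) < 0.01


class TestWepl:
    def test_uniform_density_is_linear(self):
        dens = DoseGrid(origin=(0, 0, 1.0), spacing=(10, 10, 2.0),
                        dims=(1, 1, 60))
        dens.data[:] = 1.0
        wm = wepl_along_axis((0, 0, 0), (0, 0, 1.0), dens, max_length=100.0)
        assert wm(50.0) == pytest.approx(50.0, rel=1e-9)
        dens.data[:] = 0.3
        wm = wepl_along_axis((0, 0, 0), (0, 0, 1.0), dens, max_length=100.0)
        assert wm(50.0) == pytest.approx(15.0, rel=1e-9)

    def test_two_slab_piecewise_linear(self):
        dens = DoseGrid(origin=(0, 0, 1.0), spacing=(10, 10, 2.0),
                        dims=(1, 1, 50))
        dens.data[0, 0, :25] = 1.0   # water slab, 0-50 mm
        dens.data[0, 0, 25:] = 0.5   # half density beyond
        wm = wepl_along_axis((0, 0, 0), (0, 0, 1.0), dens, max_length=100.0)
        assert wm(40.0) == pytest.approx(40.0, rel=1e-9)
        assert wm(50.0) == pytest.approx(50.0, rel=1e-9)
        assert wm(80.0) == pytest.approx(50.0 + 0.5 * 30.0, rel=1e-9)

    def test_monotone_mapping(self):
        dens = DoseGrid(origin=(0, 0, 1.0), spacing=(10, 10, 2.0),
                        dims=(1, 1, 50))
        dens.data[:] = np.linspace(0.2, 1.5, 50).reshape(1, 1, 50)
        wm = wepl_along_axis((0, 0, 0), (0, 0, 1.0), dens, max_length=100.0)
        assert np.all(np.diff(wm.wet) >= 0)

    def test_rejects_non_unit_direction(self):
        dens = DoseGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(1, 1, 5))
        with pytest.raises(c.InvalidParameterError):
            wepl_along_axis((0, 0, 0), (0, 0, 2.0), dens)
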