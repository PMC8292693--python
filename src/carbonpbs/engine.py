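"""Triple-Gaussian pencil-beam superposition onto a dose grid.

Each scanning beam deposits dose as three laterally Gaussian components: the
primary ^12C core (anisotropic, Fermi-Eyges widths), the near fragment halo
(isotropic, hyperbolic width model) and the far fragment halo (isotropic,
fixed 25 mm width).  The dose at a point is

    d = sum_j w_j sum_n IDD_n(z) G_n(x - x_j, y - y_j; sigma_n(z))

with the IDDs in Gy mm^2/MU and the Gaussians normalized to unit plane
integral (mm^-2), so the product is in Gy.  Depth z is water-equivalent
depth from the phantom surface; lateral coordinates are at the isocenter
plane with the beam along +z.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .biology import RadiationQuality
from .depthdose import DepthDoseSet
from .errors import InvalidParameterError
from .lateral import (FragmentIddModel, FragmentSigmaModel, PhaseSpace,
                      ScatteringParams, sigma1_in_water, sigma2,
                      sigma2_with_rs)

log = logging.getLogger(__name__)

# Lateral evaluation cutoffs, in units of sigma (speed/accuracy trade-off).
CUTOFF_SIGMA = {1: 5.0, 2: 5.0, 3: 4.0}

# Fixed phase-space splitting of the first component: one central sub-beam
# plus rings of 6 and 12.  Offsets are in units of the local sigma, widths
# are WIDTH_FRACTION times the local sigma; the weights reproduce a unit
# Gaussian to within 0.7% wherever the profile exceeds 5% of its peak
# (non-negative least-squares fit, frozen here).
_SPLIT_WIDTH_FRACTION = 0.75
_SPLIT_R1 = 0.59864996
_SPLIT_R2 = 1.44897963
_SPLIT_W1 = 0.118990610
_SPLIT_W2 = 0.023838016
_SPLIT_W0 = 1.0 - 6.0 * _SPLIT_W1 - 12.0 * _SPLIT_W2


@dataclass
class BeamRecord:
    """One scanning beam: depth-dose set, optics, fragment models, quality.

    ``water_range`` is the beam's range in water including the shifter
    (i.e. the Bragg-peak depth z_p); the fragment models carry the peak depth
    of the parent (shifter-free) beam, and the engine applies the depth-shift
    rules for the shifter thickness ``shifter_wet``.
    """

    beam_id: str
    energy: float                      # MeV/n, nominal accelerator energy
    shifter_wet: float                 # mm water-equivalent
    water_range: float                 # mm, peak depth with shifter
    dds: DepthDoseSet
    phase_space: PhaseSpace            # at the surface, shifter included
    base_phase_space: PhaseSpace       # shifter-free beam, same energy
    scattering: ScatteringParams
    sigma_model: FragmentSigmaModel    # zp = parent peak depth
    idd_model: FragmentIddModel        # zp = parent peak depth
    quality: Optional[RadiationQuality] = None
    _cache: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.dds.absolute:
            raise InvalidParameterError("BeamRecord requires an absolute DepthDoseSet")
        if self.dds.idd2 is None or self.dds.idd3 is None:
            raise InvalidParameterError("BeamRecord requires decomposed idd2/idd3")

    def _profiles(self):
        if "s1x" not in self._cache:
            z = self.dds.z
            s1x, s1y = sigma1_in_water(self.phase_space, self.water_range,
                                       self.scattering, z)
            if self.shifter_wet > 0:
                zs = z + self.shifter_wet
                p1x, p1y = sigma1_in_water(
                    self.base_phase_space,
                    self.water_range + self.shifter_wet, self.scattering, zs)
                # isotropic equivalent for the halo width rule
                own = np.sqrt(0.5 * (s1x ** 2 + s1y ** 2))
                par = np.sqrt(0.5 * (p1x ** 2 + p1y ** 2))
                s2 = sigma2_with_rs(z, self.shifter_wet, self.sigma_model,
                                    own, par)
            else:
                s2 = sigma2(z, self.sigma_model)
            self._cache.update(s1x=s1x, s1y=s1y, s2=s2)
        return self._cache["s1x"], self._cache["s1y"], self._cache["s2"]

    def sigmas(self, z):
        """(sigma1x, sigma1y, sigma2, sigma3) at water depth(s) z, in mm."""
        z = np.asarray(z, dtype=float)
        s1x, s1y, s2 = self._profiles()
        zg = self.dds.z
        return (np.interp(z, zg, s1x), np.interp(z, zg, s1y),
                np.interp(z, zg, s2),
                np.full_like(z, self.sigma_model.sigma3, dtype=float))


@dataclass(frozen=True)
class Spot:
    """One scanned spot: lateral position at the isocenter and its MU weight."""

    x: float
    y: float
    beam_id: str
    w: float

    def __post_init__(self) -> None:
        if self.w < 0:
            raise InvalidParameterError("spot weight must be >= 0")


@dataclass
class SpotList:
    """A plan's spots plus the prescription scale factor they were scaled by.

    The scale factor travels with the spots: a spot file without it cannot
    reproduce the clinical dose.
    """

    spots: List[Spot]
    f_scale: float = 1.0

    def __len__(self) -> int:
        return len(self.spots)

    def by_beam(self) -> Dict[str, tuple]:
        """Group spots into per-beam coordinate/weight arrays."""
        groups: Dict[str, list] = {}
        for s in self.spots:
            groups.setdefault(s.beam_id, []).append(s)
        out = {}
        for bid, ss in groups.items():
            out[bid] = (np.array([s.x for s in ss]),
                        np.array([s.y for s in ss]),
                        np.array([s.w for s in ss]))
        return out

    def scaled(self, factor: float) -> "SpotList":
        return SpotList(
            spots=[Spot(s.x, s.y, s.beam_id, s.w * factor) for s in self.spots],
            f_scale=self.f_scale * factor)


@dataclass
class DoseGrid:
    """Regular voxel grid with voxel-center sampling."""

    origin: np.ndarray    # mm, center of voxel (0,0,0)
    spacing: np.ndarray   # mm
    dims: tuple           # (nx, ny, nz)
    data: np.ndarray = None  # Gy

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.dims = tuple(int(d) for d in self.dims)
        if self.data is None:
            self.data = np.zeros(self.dims)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.dims:
            raise InvalidParameterError("DoseGrid data shape mismatch")

    def axis(self, i: int) -> np.ndarray:
        return self.origin[i] + self.spacing[i] * np.arange(self.dims[i])


@dataclass
class SubBeamSet:
    """Fixed-count phase-space splitting of the first component.

    Offsets are dimensionless (units of the local sigma per axis) and the
    sub-beam width is ``width_fraction`` times the local sigma, so the
    splitting is exact at every depth in homogeneous media up to the frozen
    mixture error.
    """

    offsets: np.ndarray        # (n, 2) dimensionless
    weights: np.ndarray        # (n,), sums to 1
    width_fraction: float

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not math.isclose(float(self.weights.sum()), 1.0, rel_tol=1e-9):
            raise InvalidParameterError("sub-beam weights must sum to 1")


def lateral_gaussian(point, center, component: int, sigmas) -> float:
    """Normalized lateral Gaussian (mm^-2) of one triple-Gaussian component.

    Component 1 is anisotropic with ``sigmas = (sigma_x, sigma_y)``;
    components 2 and 3 are isotropic with a scalar sigma.
    """
    dx = point[0] - center[0]
    dy = point[1] - center[1]
    if component == 1:
        sx, sy = sigmas
        if sx <= 0 or sy <= 0:
            raise InvalidParameterError("sigma must be > 0")
        return (math.exp(-dx ** 2 / (2 * sx ** 2) - dy ** 2 / (2 * sy ** 2))
                / (2 * math.pi * sx * sy))
    elif component in (2, 3):
        s = float(sigmas) if np.isscalar(sigmas) else float(np.asarray(sigmas).ravel()[0])
        if s <= 0:
            raise InvalidParameterError("sigma must be > 0")
        return math.exp(-(dx ** 2 + dy ** 2) / (2 * s ** 2)) / (2 * math.pi * s ** 2)
    raise InvalidParameterError("component must be 1, 2 or 3")


def dose_components_at_points(beam: BeamRecord, xs, ys, ws, px, py, pz):
    """Component doses (d1, d2, d3) at points from one beam's spots.

    ``xs, ys, ws`` are the beam's spot coordinates/weights; ``px, py, pz``
    the evaluation points (pz in water-equivalent mm).  Vectorized over
    points x spots.  Depths outside the beam's data range contribute zero.
    """
    px = np.atleast_1d(np.asarray(px, dtype=float))
    py = np.atleast_1d(np.asarray(py, dtype=float))
    pz = np.atleast_1d(np.asarray(pz, dtype=float))
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    ws = np.asarray(ws, dtype=float)

    s1x, s1y, s2, s3 = beam.sigmas(pz)
    idd1 = beam.dds.interp("idd1", pz)
    idd2 = beam.dds.interp("idd2", pz)
    idd3 = beam.dds.interp("idd3", pz)

    dx = px[:, None] - xs[None, :]
    dy = py[:, None] - ys[None, :]

    g1 = (np.exp(-dx ** 2 / (2 * s1x[:, None] ** 2)
                 - dy ** 2 / (2 * s1y[:, None] ** 2))
          / (2 * np.pi * s1x[:, None] * s1y[:, None]))
    r2 = dx ** 2 + dy ** 2
    g2 = np.exp(-r2 / (2 * s2[:, None] ** 2)) / (2 * np.pi * s2[:, None] ** 2)
    g3 = np.exp(-r2 / (2 * s3[:, None] ** 2)) / (2 * np.pi * s3[:, None] ** 2)

    d1 = idd1 * (g1 @ ws)
    d2 = idd2 * (g2 @ ws)
    d3 = idd3 * (g3 @ ws)
    return d1, d2, d3


def pencil_dose_components(point, beam: BeamRecord, w: float,
                           center=(0.0, 0.0)):
    """Component doses (d1, d2, d3) at ``point`` from one spot of weight w MU."""
    d1, d2, d3 = dose_components_at_points(
        beam, [center[0]], [center[1]], [w],
        [point[0]], [point[1]], [point[2]])
    return float(d1[0]), float(d2[0]), float(d3[0])


def pencil_dose(point, beam: BeamRecord, w: float, center=(0.0, 0.0)) -> float:
    """Dose (Gy) at ``point`` from a single pencil beam of weight w MU.

    Depths outside the beam's data range contribute zero (logged at debug
    level by the interpolation returning zero fill values).
    """
    return sum(pencil_dose_components(point, beam, w, center))


def total_dose(grid: DoseGrid, spot_list: SpotList,
               beams: Dict[str, BeamRecord],
               density: float = 1.0) -> DoseGrid:
    """Superpose all spots onto a dose grid (homogeneous medium).

    ``density`` is a uniform relative (water = 1) density: water-equivalent
    depth is density * z.  The per-slice sum over a beam's spots factorizes
    into separable x/y Gaussian matrices, evaluated as one matrix product
    per component.  Deterministic and independent of spot order.
    """
    out = DoseGrid(grid.origin.copy(), grid.spacing.copy(), grid.dims)
    gx = grid.axis(0)
    gy = grid.axis(1)
    gz = grid.axis(2)
    z_wet = density * gz

    groups = spot_list.by_beam()
    for bid, (xs, ys, ws) in groups.items():
        if bid not in beams:
            raise InvalidParameterError(f"unknown beam id {bid!r} in spot list")
        beam = beams[bid]
        s1x_a, s1y_a, s2_a, s3_a = beam.sigmas(z_wet)
        idd1_a = beam.dds.interp("idd1", z_wet)
        idd2_a = beam.dds.interp("idd2", z_wet)
        idd3_a = beam.dds.interp("idd3", z_wet)
        peak = max(beam.dds.idd_total.max(), 1e-300)
        for k in range(len(gz)):
            if idd1_a[k] + idd2_a[k] + idd3_a[k] < 1e-9 * peak:
                continue
            slice_ = out.data[:, :, k]
            for comp, idd, sx, sy in (
                    (1, idd1_a[k], s1x_a[k], s1y_a[k]),
                    (2, idd2_a[k], s2_a[k], s2_a[k]),
                    (3, idd3_a[k], s3_a[k], s3_a[k])):
                if idd <= 0:
                    continue
                cut = CUTOFF_SIGMA[comp]
                ux = (gx[:, None] - xs[None, :]) / sx
                uy = (gy[:, None] - ys[None, :]) / sy
                mx = np.exp(-0.5 * ux ** 2) / (math.sqrt(2 * math.pi) * sx)
                my = np.exp(-0.5 * uy ** 2) / (math.sqrt(2 * math.pi) * sy)
                mx[np.abs(ux) > cut] = 0.0
                my[np.abs(uy) > cut] = 0.0
                slice_ += idd * (mx @ (ws[:, None] * my.T))
    return out


def split_beam(beam: BeamRecord, density_grid=None) -> SubBeamSet:
    """Fixed 19-sub-beam phase-space splitting of the first component.

    The count and layout are independent of geometry; ``density_grid`` is
    accepted for interface symmetry with heterogeneous calculations.
    """
    offs = [(0.0, 0.0)]
    for k in range(6):
        a = 2 * math.pi * k / 6
        offs.append((_SPLIT_R1 * math.cos(a), _SPLIT_R1 * math.sin(a)))
    for k in range(12):
        a = 2 * math.pi * (k + 0.5) / 12
        offs.append((_SPLIT_R2 * math.cos(a), _SPLIT_R2 * math.sin(a)))
    weights = np.array([_SPLIT_W0] + [_SPLIT_W1] * 6 + [_SPLIT_W2] * 12)
    return SubBeamSet(offsets=np.array(offs), weights=weights,
                      width_fraction=_SPLIT_WIDTH_FRACTION)


def first_component_profile_split(beam: BeamRecord, subset: SubBeamSet,
                                  x, y, z):
    """First-component lateral density (mm^-2) rebuilt from the sub-beams.

    Offsets scale with the local sigma per axis, widths by the fixed
    fraction, so the recombination holds at every depth in water.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s1x, s1y, _, _ = beam.sigmas(np.atleast_1d(z))
    sx, sy = float(s1x[0]), float(s1y[0])
    ssx, ssy = subset.width_fraction * sx, subset.width_fraction * sy
    out = np.zeros(np.broadcast(x, y).shape)
    for (ux, uy), w in zip(subset.offsets, subset.weights):
        out = out + w * np.exp(-(x - ux * sx) ** 2 / (2 * ssx ** 2)
                               - (y - uy * sy) ** 2 / (2 * ssy ** 2)) \
            / (2 * np.pi * ssx * ssy)
    return out


@dataclass
class WeplMap:
    """Monotone mapping from geometric depth along a ray to water depth."""

    t: np.ndarray       # geometric distance from entry, mm
    wet: np.ndarray     # cumulative water-equivalent depth, mm

    def __call__(self, t):
        return np.interp(np.asarray(t, dtype=float), self.t, self.wet)


def wepl_along_axis(entry, direction, density_grid: DoseGrid,
                    step: Optional[float] = None,
                    max_length: Optional[float] = None) -> WeplMap:
    """Integrate relative density along a ray to build a WEPL mapping.

    ``density_grid`` holds relative densities (water = 1) in its ``data``.
    Midpoint sampling with a step of one tenth of the smallest voxel spacing
    (exact for voxel-aligned slabs).  Beyond the grid the last sampled
    density is extended, with a warning.
    """
    entry = np.asarray(entry, dtype=float)
    direction = np.asarray(direction, dtype=float)
    n = np.linalg.norm(direction)
    if not math.isclose(n, 1.0, rel_tol=1e-6):
        raise InvalidParameterError("direction must be a unit vector")
    if step is None:
        step = float(density_grid.spacing.min()) / 10.0
    if max_length is None:
        max_length = float(np.sum(density_grid.spacing * density_grid.dims)) + 1.0

    nsteps = int(math.ceil(max_length / step))
    ts = step * np.arange(nsteps + 1)
    mids = entry[None, :] + direction[None, :] * (ts[:-1] + step / 2)[:, None]
    idx = np.round((mids - density_grid.origin[None, :])
                   / density_grid.spacing[None, :]).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(density_grid.dims)), axis=1)
    rho = np.empty(nsteps)
    last = 1.0
    exited = False
    for i in range(nsteps):
        if inside[i]:
            last = density_grid.data[tuple(idx[i])]
        else:
            exited = True
        rho[i] = last
    if exited:
        log.warning("wepl_along_axis: ray leaves the density grid; "
                    "extending with the last sampled density")
    wet = np.concatenate([[0.0], np.cumsum(rho * step)])
    return WeplMap(t=ts, wet=wet)
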