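"""Lateral beam-size models: Fermi-Eyges transport and the fragment halo.

The first (primary ^12C) component evolves according to Fermi-Eyges theory:
the second moments (sigma11, sigma12, sigma22) of the transverse phase space
drift ballistically and grow by multiple Coulomb scattering, whose angular
increment over a water step follows Kanematsu's treatment-planning form

    dtheta^2 = C * Z^-0.16 * A^-0.92 * ln(R/R')

with R, R' the residual ranges before/after the step.  The fragment halo is
described by two isotropic Gaussians: sigma2(z) follows a hyperbolic form
anchored at the Bragg-peak depth, sigma3 is fixed (25 mm), and the third
component's depth curve IDD3(z) follows a saturating-exponential build-up
with an exponential fall-off beyond the peak.  Range shifters of
water-equivalent thickness L shift the fragment curves in depth and widen
sigma2 by the same squared-size increment as the first component.

Note on the adopted functional forms: the grouping of the shape constants in
the sigma2 and IDD3 formulas is isolated in :func:`sigma2` and :func:`idd3`
so an alternative grouping is a one-line change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import FitFailureError, InvalidParameterError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AxisMoments:
    """Second moments of one transverse axis: position variance (mm^2),
    position-angle covariance (mm rad), angular variance (rad^2)."""

    s11: float
    s12: float
    s22: float

    def __post_init__(self) -> None:
        if self.s11 < 0 or self.s22 < 0:
            raise InvalidParameterError("sigma11 and sigma22 must be >= 0")
        if self.s11 * self.s22 - self.s12 ** 2 < -1e-12:
            raise InvalidParameterError("phase-space determinant must be >= 0")

    @property
    def sigma(self) -> float:
        return math.sqrt(self.s11)


@dataclass(frozen=True)
class PhaseSpace:
    """Transverse phase space of a beam at a reference plane (z = 0)."""

    x: AxisMoments
    y: AxisMoments


@dataclass(frozen=True)
class ScatteringParams:
    """Kanematsu scattering-power parameters for the incident ion."""

    C: float = 0.0015
    Z: int = 6
    A: int = 12

    def __post_init__(self) -> None:
        if self.C <= 0 or self.Z <= 0 or self.A <= 0:
            raise InvalidParameterError("scattering parameters must be > 0")


@dataclass(frozen=True)
class FragmentSigmaModel:
    """Hyperbolic sigma2(z) model constants plus the fixed sigma3."""

    c1: float = 5.0       # mm, plateau width
    c2: float = 30.0      # mm, onset distance upstream of the peak
    c3: float = 0.006     # dimensionless growth constant
    zp: float = 300.0     # mm, Bragg-peak depth
    sigma3: float = 25.0  # mm, fixed third-component width

    def __post_init__(self) -> None:
        if self.c1 <= 0 or self.c2 <= 0 or self.sigma3 <= 0:
            raise InvalidParameterError("c1, c2, sigma3 must be > 0")
        if self.c3 < 0:
            raise InvalidParameterError("c3 must be >= 0")


@dataclass(frozen=True)
class FragmentIddModel:
    """Saturating-exponential IDD3(z) model constants."""

    c4: float = 21.0    # Gy mm^2/MU, saturation level
    c5: float = 500.0   # mm, build-up length
    c6: float = 1.5     # dimensionless distal decay constant
    zp: float = 300.0   # mm, Bragg-peak depth

    def __post_init__(self) -> None:
        if min(self.c4, self.c5, self.c6, self.zp) <= 0:
            raise InvalidParameterError("all FragmentIddModel fields must be > 0")


def scattering_increment(sp: ScatteringParams, R: float, R_prime: float) -> float:
    """Angular-variance increment (rad^2) over a step from residual range R to R'."""
    if not 0 < R_prime <= R:
        raise InvalidParameterError("require 0 < R' <= R")
    return sp.C * sp.Z ** -0.16 * sp.A ** -0.92 * math.log(R / R_prime)


def transport(ps: PhaseSpace, z: float, dtheta2: float = 0.0) -> tuple[PhaseSpace, float, float]:
    """Fermi-Eyges transport over a homogeneous segment of length z.

    Returns the phase space at z plus the beam sizes sigma_x, sigma_y
    (sqrt of the position variances).
    """
    if z < 0:
        raise InvalidParameterError("transport length must be >= 0")

    def step(a: AxisMoments) -> AxisMoments:
        s11 = a.s11 + 2.0 * a.s12 * z + (a.s22 + dtheta2 / 3.0) * z ** 2
        s12 = a.s12 + (a.s22 + dtheta2 / 2.0) * z
        s22 = a.s22 + dtheta2
        return AxisMoments(max(s11, 0.0), s12, s22)

    out = PhaseSpace(step(ps.x), step(ps.y))
    return out, out.x.sigma, out.y.sigma


def fit_phase_space(sizes_x, sizes_y, plane_offset: float = 200.0) -> PhaseSpace:
    """Recover isocenter phase space from in-air beam sizes at three planes.

    ``sizes_x``/``sizes_y`` are the measured 1-sigma sizes (mm) at planes
    z = -offset, 0, +offset.  In air sigma^2(z) is an exact quadratic in z,
    so the three moments follow from finite differences.  Forward drift
    reproduces the inputs exactly.
    """

    def solve(sm, s0, sp_):
        if min(sm, s0, sp_) <= 0:
            raise InvalidParameterError("beam sizes must be > 0")
        L = plane_offset
        a = s0 ** 2
        c = (sp_ ** 2 + sm ** 2 - 2.0 * s0 ** 2) / (2.0 * L ** 2)
        b = (sp_ ** 2 - sm ** 2) / (2.0 * L)
        s11, s12, s22 = a, b / 2.0, c
        if s22 < 0 or s11 * s22 - s12 ** 2 < -1e-12:
            raise FitFailureError(
                "non-physical phase-space solution (negative angular variance "
                "or determinant)")
        try:
            return AxisMoments(s11, s12, s22)
        except InvalidParameterError as exc:  # pragma: no cover - guarded above
            raise FitFailureError(str(exc)) from exc

    return PhaseSpace(solve(*sizes_x), solve(*sizes_y))


def sigma1_in_water(ps: PhaseSpace, R0: float, scat: ScatteringParams,
                    z, step: float = 1.0):
    """First-component beam sizes in water by stepwise Fermi-Eyges integration.

    The scattering increment of each step uses the local residual ranges
    R0 - z and R0 - z - dz; beyond the particle range the beam drifts
    ballistically.  Returns (sigma_x, sigma_y) interpolated onto ``z``.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    zmax = float(z.max())
    grid = [0.0]
    sx = [ps.x.sigma]
    sy = [ps.y.sigma]
    cur = ps
    pos = 0.0
    r_min = 1e-3
    while pos < zmax:
        dz = min(step, zmax - pos)
        R = max(R0 - pos, r_min)
        Rp = max(R0 - pos - dz, r_min)
        dth2 = scattering_increment(scat, R, Rp) if Rp < R else 0.0
        cur, s1x, s1y = transport(cur, dz, dth2)
        pos += dz
        grid.append(pos)
        sx.append(s1x)
        sy.append(s1y)
    gx = np.interp(z, grid, sx)
    gy = np.interp(z, grid, sy)
    return gx, gy


def sigma2(z, m: FragmentSigmaModel) -> np.ndarray:
    """Second-component (fragment halo) width without range shifters.

    Constant c1 upstream of zp - c2, hyperbolic growth
    sqrt(c1^2 + c3 (z - zp + c2)^2) beyond.  The c3 grouping (multiplying the
    squared offset) is the adopted reading of the model form; change it here
    if an alternative grouping is preferred.
    """
    z = np.asarray(z, dtype=float)
    t = z - (m.zp - m.c2)
    grow = np.sqrt(m.c1 ** 2 + m.c3 * np.maximum(t, 0.0) ** 2)
    return np.where(t <= 0.0, m.c1, grow)


def sigma2_with_rs(z, L: float, m: FragmentSigmaModel,
                   sigma1_zL, sigma1_zpL) -> np.ndarray:
    """sigma2 with a range shifter of water-equivalent thickness L.

    The squared-size increase equals that of the first component:
    sigma2(z; L)^2 = sigma2(z+L)^2 + sigma1(z; L)^2 - sigma1(z+L)^2.
    A negative radicand is clamped to sigma2(z+L) with a warning.
    """
    if L < 0:
        raise InvalidParameterError("range-shifter thickness must be >= 0")
    z = np.asarray(z, dtype=float)
    base = sigma2(z + L, m)
    rad = base ** 2 + np.asarray(sigma1_zL, dtype=float) ** 2 \
        - np.asarray(sigma1_zpL, dtype=float) ** 2
    if np.any(rad < 0):
        log.warning("sigma2_with_rs: negative radicand clamped to sigma2(z+L)")
    return np.where(rad >= 0, np.sqrt(np.maximum(rad, 0.0)), base)


def idd3(z, m: FragmentIddModel) -> np.ndarray:
    """Third-component depth curve: saturating build-up, exponential fall-off.

    c4 (1 - exp(-z/c5)) up to zp, then decay with length c6*zp (the adopted
    grouping of the distal decay constant; change it here if an alternative
    grouping is preferred).
    """
    z = np.asarray(z, dtype=float)
    build = m.c4 * (1.0 - np.exp(-np.maximum(z, 0.0) / m.c5))
    peak = m.c4 * (1.0 - math.exp(-m.zp / m.c5))
    tail = peak * np.exp(-np.maximum(z - m.zp, 0.0) / (m.c6 * m.zp))
    return np.where(z <= m.zp, build, tail)


def idd3_with_rs(z, L: float, m: FragmentIddModel) -> np.ndarray:
    """Third-component curve with a range shifter: shifted in depth by L."""
    if L < 0:
        raise InvalidParameterError("range-shifter thickness must be >= 0")
    return idd3(np.asarray(z, dtype=float) + L, m)
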