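"""Pristine Bragg-curve model, cross-section correction, and absolute scaling.

The integral depth dose (IDD, Gy mm^2/MU) of a scanning beam is the dose
integrated over the full lateral plane at each water depth z.  The primary
(^12C) component is modeled as the product of an exponentially attenuated
fluence and the range-straggled stopping power,

    IDD_12C(z) = Phi0 * 2^(-z/lambda) * int N(z'-z; sigma_strag) S(R0-z') dz'

with lambda inversely proportional to the total nuclear cross section.  When
the cross section used to score a curve is wrong, the primary curve is
corrected pointwise by 2^(-z/lambda') / 2^(-z/lambda) and the fragment curve
by the depth-independent ratio lambda/lambda'.  The absolute scale is pinned
by a dose-area-product (DAP) measurement at 2 cm depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .errors import DegenerateInputError, InvalidParameterError

log = logging.getLogger(__name__)

DEFAULT_Z_GRID = np.arange(0.0, 350.0 + 1e-9, 0.5)  # mm water


@dataclass
class StoppingPowerCurve:
    """Tabulated stopping power of the ion in water.

    ``r_grid``/``s_r`` give S as a function of residual range (mm water,
    MeV/mm); ``e_grid``/``s_e`` give S as a function of kinetic energy per
    nucleon (MeV/n, MeV/mm).  Optional exact callables (``fn_r``, ``fn_e``)
    take precedence over table interpolation when present.
    """

    r_grid: np.ndarray
    s_r: np.ndarray
    e_grid: np.ndarray
    s_e: np.ndarray
    fn_r: Optional[Callable[[np.ndarray], np.ndarray]] = None
    fn_e: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.s_r = np.asarray(self.s_r, dtype=float)
        self.e_grid = np.asarray(self.e_grid, dtype=float)
        self.s_e = np.asarray(self.s_e, dtype=float)
        if np.any(self.s_r <= 0) or np.any(self.s_e <= 0):
            raise InvalidParameterError("stopping power values must be > 0")
        if np.any(np.diff(self.r_grid) <= 0) or np.any(np.diff(self.e_grid) <= 0):
            raise InvalidParameterError("stopping power grids must be increasing")

    def s_of_r(self, r) -> np.ndarray:
        """S(r) in MeV/mm; zero for non-positive residual range."""
        r = np.asarray(r, dtype=float)
        if self.fn_r is not None:
            out = np.where(r > 0, self.fn_r(np.where(r > 0, r, 1.0)), 0.0)
        else:
            out = np.where(r > 0,
                           np.interp(r, self.r_grid, self.s_r), 0.0)
        return out

    def s_of_e(self, e) -> np.ndarray:
        """S(E) in MeV/mm for kinetic energy per nucleon E in MeV/n."""
        e = np.asarray(e, dtype=float)
        if self.fn_e is not None:
            return self.fn_e(e)
        return np.interp(e, self.e_grid, self.s_e)


@dataclass(frozen=True)
class PristineBeamParams:
    """Parameters of the attenuated, range-straggled pristine Bragg model."""

    R0: float                 # initial residual range, mm water
    lam: float                # fluence attenuation half-length lambda, mm
    lam_prime: float          # corrected lambda', mm
    sigma_strag: float        # range straggling (1 sigma), mm
    phi0: float = 1.0         # initial relative fluence

    def __post_init__(self) -> None:
        for name in ("R0", "lam", "lam_prime", "sigma_strag"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"PristineBeamParams.{name} must be > 0")


def default_sigma_strag(R0: float) -> float:
    """Bohr-like range-straggling scaling stand-in: 0.012 * R0^0.935 mm."""
    return 0.012 * R0 ** 0.935


@dataclass
class DepthDoseSet:
    """z-gridded IDD curves of one scanning beam.

    ``idd_frag`` is the chamber-side fragment curve (Eq. idd2 + eps*idd3 once
    absolute); ``idd_total = idd1 + idd_frag`` is what the chamber measures.
    ``idd2``/``idd3`` are the engine-side second/third-component curves and
    may be absent before fragment decomposition.
    """

    z: np.ndarray
    idd1: np.ndarray
    idd_frag: np.ndarray
    idd2: Optional[np.ndarray] = None
    idd3: Optional[np.ndarray] = None
    absolute: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.idd1 = np.asarray(self.idd1, dtype=float)
        self.idd_frag = np.asarray(self.idd_frag, dtype=float)
        for name in ("idd1", "idd_frag", "idd2", "idd3"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            setattr(self, name, v)
            if v.shape != self.z.shape:
                raise InvalidParameterError(f"{name} shape mismatch with z grid")
            if np.any(v < -1e-12):
                raise InvalidParameterError(f"{name} must be non-negative")

    @property
    def idd_total(self) -> np.ndarray:
        return self.idd1 + self.idd_frag

    def interp(self, curve: str, z) -> np.ndarray:
        """Linear interpolation of one stored curve; zero outside the grid."""
        vals = self.idd_total if curve == "idd_total" else getattr(self, curve)
        return np.interp(np.asarray(z, dtype=float), self.z, vals,
                         left=0.0, right=0.0)


@dataclass(frozen=True)
class DapCalibration:
    """Uniform-grid DAP measurement: dose at field center, spot spacing, MU/spot."""

    d_meas: float             # Gy
    spacing_delta: float = 3.0  # mm
    q_per_spot: float = 1.0   # MU
    depth: float = 20.0       # mm

    def __post_init__(self) -> None:
        for name in ("d_meas", "spacing_delta", "q_per_spot", "depth"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"DapCalibration.{name} must be > 0")


def fluence(z, params: PristineBeamParams) -> np.ndarray:
    """Relative ^12C fluence Phi0 * 2^(-z/lambda) surviving nuclear reactions."""
    z = np.asarray(z, dtype=float)
    return params.phi0 * np.power(2.0, -z / params.lam)


def pristine_idd(z, params: PristineBeamParams, sp: StoppingPowerCurve) -> np.ndarray:
    """Pristine ^12C IDD: attenuated fluence times straggling-convolved S(R0-z).

    The Gaussian convolution is evaluated by trapezoid quadrature over a
    +-5 sigma window.  Depths beyond R0 + 5 sigma return exactly zero.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    sig = params.sigma_strag
    step = min(0.25, sig / 5.0)
    t = np.arange(-5.0 * sig, 5.0 * sig + step / 2, step)
    kern = np.exp(-t ** 2 / (2.0 * sig ** 2)) / (math.sqrt(2.0 * math.pi) * sig)
    # S(R0 - (z + t)) on the outer product grid; the end-of-range
    # singularity of S is capped at 0.05 mm residual range so the trapezoid
    # nodes stay finite (the straggling kernel smooths it out anyway)
    rr = params.R0 - (z[:, None] + t[None, :])
    s_vals = sp.s_of_r(np.where(rr > 0, np.maximum(rr, 0.05), rr))
    conv = np.trapezoid(kern[None, :] * s_vals, dx=step, axis=1)
    out = fluence(z, params) * conv
    out[z > params.R0 + 5.0 * sig] = 0.0
    return out


def correct_idd_12c(idd, z, lam: float, lam_prime: float) -> np.ndarray:
    """Cross-section correction of the primary curve: 2^(-z/l')/2^(-z/l) pointwise."""
    if lam <= 0 or lam_prime <= 0:
        raise InvalidParameterError("lambda parameters must be > 0")
    z = np.asarray(z, dtype=float)
    factor = np.power(2.0, z / lam - z / lam_prime)
    return np.asarray(idd, dtype=float) * factor


def correct_idd_frag(idd, lam: float, lam_prime: float) -> np.ndarray:
    """Fragment curve scales linearly with the total cross section: factor lam/lam'."""
    if lam <= 0 or lam_prime <= 0:
        raise InvalidParameterError("lambda parameters must be > 0")
    return np.asarray(idd, dtype=float) * (lam / lam_prime)


def dap_from_grid(meas: DapCalibration) -> float:
    """Dose-area product per MU from a uniform-grid irradiation: D * Delta^2 / Q."""
    return meas.d_meas * meas.spacing_delta ** 2 / meas.q_per_spot


def to_absolute(dds: DepthDoseSet, dap_2cm: float, depth: float = 20.0) -> DepthDoseSet:
    """Scale all curves so the chamber total IDD equals the DAP at the given depth."""
    ref = float(dds.interp("idd_total", depth))
    if ref <= 0:
        raise DegenerateInputError("total IDD at the DAP depth is zero")
    s = dap_2cm / ref
    return DepthDoseSet(
        z=dds.z.copy(),
        idd1=dds.idd1 * s,
        idd_frag=dds.idd_frag * s,
        idd2=None if dds.idd2 is None else dds.idd2 * s,
        idd3=None if dds.idd3 is None else dds.idd3 * s,
        absolute=True,
    )


def detection_efficiency(chamber_radius_R: float, sigma3: float) -> float:
    """Fraction of a centered 2-D Gaussian (sigma3) collected by a disk of radius R.

    Closed form of the polar integral: 1 - exp(-R^2 / (2 sigma3^2)).
    """
    if chamber_radius_R <= 0 or sigma3 <= 0:
        raise InvalidParameterError("chamber radius and sigma3 must be > 0")
    return 1.0 - math.exp(-chamber_radius_R ** 2 / (2.0 * sigma3 ** 2))


def decompose_fragment(idd_frag_abs, idd3, epsilon: float) -> np.ndarray:
    """Second-component curve: chamber fragment minus eps-weighted third component.

    Negative residuals are clamped at zero; if the clamped area exceeds 5% of
    the fragment area a warning is logged (measured-minus-model residuals can
    dip below zero).
    """
    if not 0.0 < epsilon <= 1.0:
        raise InvalidParameterError("epsilon must be in (0, 1]")
    idd_frag_abs = np.asarray(idd_frag_abs, dtype=float)
    idd3 = np.asarray(idd3, dtype=float)
    raw = idd_frag_abs - epsilon * idd3
    clamped = np.maximum(raw, 0.0)
    lost = float(np.sum(clamped - raw))
    total = float(np.sum(np.abs(idd_frag_abs)))
    if total > 0 and lost > 0.05 * total:
        log.warning("fragment decomposition clamped %.1f%% of fragment area",
                    100.0 * lost / total)
    return clamped
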