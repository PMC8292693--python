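"""Beam-modeling procedures: frame-pattern fragment fits, cross-section
correction, absolute normalization, per-beam correction factors, LQ fits.

The fragment halo of a scanning beam cannot be separated from the primary
core by on-axis measurements, so the facility irradiates hollow square
"frame" patterns of spots and measures the dose at the field center: the
primary component barely reaches the center from the frame, while the two
halo Gaussians do.  Fitting the center doses of several frames at several
depths yields per-depth (IDD2, IDD3, sigma2, sigma3), which are then
condensed into analytic depth models.  A second fit pass fixes sigma3 at
25 mm, its observed depth-independent value.

The module also provides the chain that turns a raw measurement set into an
engine-ready beam library: attenuation-length correction of the scored
curves against chamber measurements, DAP normalization to absolute units,
fragment decomposition with the chamber detection efficiency, phase-space
recovery from three-plane in-air sizes, and the per-beam integral-dose
normalization factors (IDNF) against volume irradiations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import optimize

from .depthdose import (DepthDoseSet, correct_idd_12c, correct_idd_frag,
                        dap_from_grid, decompose_fragment,
                        detection_efficiency, to_absolute)
from .engine import BeamRecord, SpotList, dose_components_at_points
from .errors import FitFailureError, InvalidParameterError
from .lateral import (FragmentIddModel, FragmentSigmaModel, PhaseSpace,
                      fit_phase_space, idd3 as idd3_curve)
from .library import BeamLibrary
from .synthetic import CHAMBER_RADIUS_MM, MeasurementSet

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# frame patterns

@dataclass
class FramePattern:
    """Square frame of spots: grid points with inner <= max(|x|,|y|) <= outer."""

    inner: float
    outer: float
    spacing: float
    spots: np.ndarray  # (n, 2) mm

    @property
    def count(self) -> int:
        return len(self.spots)


def generate_frame_pattern(inner: float, outer: float,
                           spacing: float = 3.0) -> FramePattern:
    """Spot positions of a frame pattern (inner = 0 gives the filled square)."""
    if spacing <= 0 or inner < 0 or outer < inner:
        raise InvalidParameterError("require 0 <= inner <= outer, spacing > 0")
    for v, name in ((inner, "inner"), (outer, "outer")):
        if abs(v / spacing - round(v / spacing)) > 1e-9:
            raise InvalidParameterError(f"{name} must be a multiple of spacing")
    n = int(round(outer / spacing))
    coords = spacing * np.arange(-n, n + 1)
    X, Y = np.meshgrid(coords, coords)
    cheb = np.maximum(np.abs(X), np.abs(Y))
    mask = (cheb >= inner - 1e-9) & (cheb <= outer + 1e-9)
    spots = np.stack([X[mask], Y[mask]], axis=1)
    return FramePattern(inner=inner, outer=outer, spacing=spacing, spots=spots)


# Table of the facility's seven frame patterns (inner, outer), 3-mm spacing.
STANDARD_PATTERNS = {
    "A": (0.0, 12.0), "B": (12.0, 18.0), "C": (18.0, 24.0),
    "D": (24.0, 30.0), "E": (30.0, 36.0), "F": (36.0, 42.0),
    "G": (42.0, 48.0),
}


@dataclass(frozen=True)
class FrameMeasurement:
    """Center dose of one frame irradiation."""

    beam_id: str
    pattern_id: str
    depth: float      # mm water
    dose: float       # Gy
    w_per_spot: float  # MU

    def __post_init__(self) -> None:
        if self.dose < 0 or self.w_per_spot <= 0:
            raise InvalidParameterError("dose >= 0 and w_per_spot > 0 required")


def frame_center_dose(pattern: FramePattern, beam: BeamRecord, z: float,
                      w_per_spot: float) -> float:
    """Engine-evaluated dose at the field center for a frame irradiation."""
    if pattern.count == 0:
        raise InvalidParameterError("empty frame pattern")
    xs, ys = pattern.spots[:, 0], pattern.spots[:, 1]
    ws = np.full(pattern.count, w_per_spot)
    d1, d2, d3 = dose_components_at_points(beam, xs, ys, ws, [0.0], [0.0], [z])
    return float(d1[0] + d2[0] + d3[0])


# ---------------------------------------------------------------------------
# fragment-parameter extraction

@dataclass
class FragmentDepthFit:
    """Per-depth fragment parameters recovered from frame measurements."""

    depth: float
    idd2: float
    idd3: float
    sigma2: float
    sigma3: float
    residual: float


def _halo_geometry_factors(patterns: Dict[str, FramePattern], sigma: float
                           ) -> Dict[str, float]:
    """Sum over a pattern's spots of the isotropic Gaussian at the origin."""
    out = {}
    for pid, pat in patterns.items():
        r2 = np.sum(pat.spots ** 2, axis=1)
        out[pid] = float(np.sum(np.exp(-r2 / (2 * sigma ** 2)))
                         / (2 * math.pi * sigma ** 2))
    return out


def fit_fragment_components(measurements: Sequence[FrameMeasurement],
                            beam: BeamRecord,
                            patterns: Optional[Dict[str, FramePattern]] = None,
                            sigma3_fixed: float = 25.0,
                            seed: int = 0) -> List[FragmentDepthFit]:
    """Recover per-depth (IDD2, IDD3, sigma2, sigma3) from frame center doses.

    The first component's contribution is computed from the already-modeled
    IDD1 and sigma1 and subtracted.  A free four-parameter fit per depth is
    followed by a second pass with sigma3 fixed (its fitted values are
    depth-independent in practice).  Residuals are relative to the measured
    dose.  Requires at least four patterns per depth.
    """
    if patterns is None:
        patterns = {pid: generate_frame_pattern(i, o)
                    for pid, (i, o) in STANDARD_PATTERNS.items()}
    by_depth: Dict[float, List[FrameMeasurement]] = {}
    for m in measurements:
        by_depth.setdefault(m.depth, []).append(m)

    rng = np.random.default_rng(seed)
    fits: List[FragmentDepthFit] = []
    for depth in sorted(by_depth):
        ms = by_depth[depth]
        if len(ms) < 4:
            raise InvalidParameterError(
                f"need >= 4 patterns at depth {depth}, got {len(ms)}")
        doses = np.array([m.dose for m in ms])
        wps = np.array([m.w_per_spot for m in ms])
        # first-component center dose per MU for each pattern
        comp1 = np.empty(len(ms))
        for i, m in enumerate(ms):
            pat = patterns[m.pattern_id]
            d1, _, _ = dose_components_at_points(
                beam, pat.spots[:, 0], pat.spots[:, 1],
                np.full(pat.count, 1.0), [0.0], [0.0], [depth])
            comp1[i] = float(d1[0])
        halo_meas = doses - comp1 * wps
        scale = np.maximum(doses, 1e-300)

        def residuals(p, s3_fix=None):
            i2, i3, s2 = p[0], p[1], p[2]
            s3 = p[3] if s3_fix is None else s3_fix
            if s2 <= 0.1 or s3 <= 0.1:
                return np.full(len(ms), 1e6)
            g2 = _halo_geometry_factors(
                {m.pattern_id: patterns[m.pattern_id] for m in ms}, s2)
            g3 = _halo_geometry_factors(
                {m.pattern_id: patterns[m.pattern_id] for m in ms}, s3)
            model = np.array([(i2 * g2[m.pattern_id] + i3 * g3[m.pattern_id])
                              * m.w_per_spot for m in ms])
            return (model - halo_meas) / scale

        idd2_ref = max(float(beam.dds.interp("idd2", depth)), 1e-3)
        idd3_ref = max(float(beam.dds.interp("idd3", depth)), 1e-3)
        best = None
        for start in range(3):
            jitter = 1.0 if start == 0 else float(rng.uniform(0.5, 2.0))
            x0 = np.array([idd2_ref * jitter, idd3_ref * jitter,
                           8.0 * jitter, 25.0])
            try:
                sol = optimize.least_squares(
                    residuals, x0,
                    bounds=([0.0, 0.0, 0.5, 5.0], [1e4, 1e4, 60.0, 60.0]))
            except Exception:  # noqa: BLE001 - treated as a failed start
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success and best.cost > 1e-3:
            raise FitFailureError(f"frame fit failed at depth {depth}")
        # second pass: sigma3 fixed
        sol2 = optimize.least_squares(
            lambda p: residuals(p, s3_fix=sigma3_fixed), best.x[:3],
            bounds=([0.0, 0.0, 0.5], [1e4, 1e4, 60.0]))
        if not sol2.success and sol2.cost > 1e-3:
            raise FitFailureError(
                f"constrained frame fit failed at depth {depth}: "
                f"residual {math.sqrt(2 * sol2.cost):.3g}")
        fits.append(FragmentDepthFit(
            depth=depth, idd2=float(sol2.x[0]), idd3=float(sol2.x[1]),
            sigma2=float(sol2.x[2]), sigma3=sigma3_fixed,
            residual=float(np.sqrt(np.mean(sol2.fun ** 2)))))
    return fits


def fit_sigma2_function(depths, sigma2_values, zp, seed: int = 0
                        ) -> FragmentSigmaModel:
    """Least-squares fit of the hyperbolic sigma2(z) constants (c1, c2, c3).

    ``zp`` may be a scalar or one peak depth per sample; the returned model
    carries the reference peak depth (the largest supplied).
    """
    depths = np.asarray(depths, dtype=float)
    sig = np.asarray(sigma2_values, dtype=float)
    zps = np.broadcast_to(np.asarray(zp, dtype=float), depths.shape)
    if len(depths) < 6:
        raise InvalidParameterError("need at least 6 depth samples")
    zp_ref = float(zps.max())

    def resid(p):
        c1, c2, c3 = p
        if c1 <= 0 or c2 <= 0 or c3 < 0:
            return np.full(len(depths), 1e6)
        t = depths - (zps - c2)
        model = np.where(t <= 0, c1, np.sqrt(c1 ** 2 + c3 * np.maximum(t, 0) ** 2))
        return model - sig

    best = None
    rng = np.random.default_rng(seed)
    for start in range(3):
        jitter = 1.0 if start == 0 else float(rng.uniform(0.5, 2.0))
        x0 = np.array([max(sig.min(), 0.5) * jitter, 30.0 * jitter,
                       0.006 * jitter])
        sol = optimize.least_squares(resid, x0,
                                     bounds=([0.1, 1.0, 0.0], [50.0, 200.0, 1.0]))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not (best.success or best.cost < 1e-6):
        raise FitFailureError("sigma2 model fit did not converge")
    return FragmentSigmaModel(c1=float(best.x[0]), c2=float(best.x[1]),
                              c3=float(best.x[2]), zp=zp_ref)


def fit_idd3_function(depths, idd3_values, zp, seed: int = 0) -> FragmentIddModel:
    """Least-squares fit of the IDD3(z) constants (c4, c5, c6)."""
    depths = np.asarray(depths, dtype=float)
    vals = np.asarray(idd3_values, dtype=float)
    zps = np.broadcast_to(np.asarray(zp, dtype=float), depths.shape)
    if len(depths) < 6:
        raise InvalidParameterError("need at least 6 depth samples")
    zp_ref = float(zps.max())

    def resid(p):
        c4, c5, c6 = p
        if min(c4, c5, c6) <= 0:
            return np.full(len(depths), 1e6)
        build = c4 * (1.0 - np.exp(-depths / c5))
        peak = c4 * (1.0 - np.exp(-zps / c5))
        tail = peak * np.exp(-np.maximum(depths - zps, 0.0) / (c6 * zps))
        return np.where(depths <= zps, build, tail) - vals

    best = None
    rng = np.random.default_rng(seed)
    for start in range(3):
        jitter = 1.0 if start == 0 else float(rng.uniform(0.5, 2.0))
        x0 = np.array([max(vals.max(), 0.1) * 2.0 * jitter, 400.0 * jitter,
                       1.0 * jitter])
        sol = optimize.least_squares(
            resid, x0, bounds=([1e-3, 10.0, 0.05], [1e3, 5e3, 20.0]))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not (best.success or best.cost < 1e-9):
        raise FitFailureError("IDD3 model fit did not converge")
    return FragmentIddModel(c4=float(best.x[0]), c5=float(best.x[1]),
                            c6=float(best.x[2]), zp=zp_ref)


# ---------------------------------------------------------------------------
# attenuation-length correction and chain orchestration

def fit_lambda_correction(z, raw_idd_12c, raw_idd_frag, chamber_idd,
                          lam_raw: float,
                          bounds: tuple = (60.0, 400.0)) -> float:
    """Corrected attenuation half-length lambda' matching the chamber curve.

    Minimizes the relative residual between the corrected model total
    (primary corrected pointwise, fragment scaled by lam/lam') and the
    chamber measurement.
    """
    z = np.asarray(z, dtype=float)
    scale = np.maximum(np.asarray(chamber_idd, dtype=float), 1e-300)

    def cost(lam_p):
        model = (correct_idd_12c(raw_idd_12c, z, lam_raw, lam_p)
                 + correct_idd_frag(raw_idd_frag, lam_raw, lam_p))
        return float(np.sum(((model - chamber_idd) / scale) ** 2))

    sol = optimize.minimize_scalar(cost, bounds=bounds, method="bounded",
                                   options={"xatol": 1e-4})
    if not sol.success:
        raise FitFailureError("lambda correction fit did not converge")
    return float(sol.x)


def estimate_peak_depth(z, idd_total) -> float:
    """Bragg-peak depth by quadratic refinement around the curve maximum."""
    z = np.asarray(z, dtype=float)
    y = np.asarray(idd_total, dtype=float)
    i = int(np.argmax(y))
    if 0 < i < len(z) - 1:
        num = (y[i - 1] - y[i + 1]) * (z[i + 1] - z[i - 1])
        den = 2.0 * (y[i - 1] - 2 * y[i] + y[i + 1])
        if den != 0:
            return float(z[i] + 0.25 * num / den)
    return float(z[i])


def model_beam_library(mset: MeasurementSet,
                       frame_measurements: Sequence[FrameMeasurement],
                       seed: int = 0) -> BeamLibrary:
    """Full modeling chain: raw measurement set to engine-ready library.

    Steps per beam: lambda' correction of the scored curves against the
    chamber IDD, DAP normalization to Gy mm^2/MU, phase-space recovery from
    three-plane in-air sizes.  Fragment halo constants are fitted globally
    from the supplied frame measurements, then IDD3 is rebuilt from the
    fitted model and IDD2 by decomposition with the chamber detection
    efficiency.
    """
    eps_sigma3 = 25.0
    eps = detection_efficiency(CHAMBER_RADIUS_MM, eps_sigma3)

    # --- per-beam corrections and absolute scaling ---
    corrected: Dict[str, DepthDoseSet] = {}
    phase: Dict[str, PhaseSpace] = {}
    zp_est: Dict[str, float] = {}
    for bid, bm in mset.beams.items():
        lam_p = fit_lambda_correction(bm.z, bm.raw_idd_12c, bm.raw_idd_frag,
                                      bm.chamber_idd, mset.lam_raw)
        idd1 = correct_idd_12c(bm.raw_idd_12c, bm.z, mset.lam_raw, lam_p)
        frag = correct_idd_frag(bm.raw_idd_frag, mset.lam_raw, lam_p)
        rel = DepthDoseSet(z=bm.z, idd1=idd1, idd_frag=frag, absolute=False)
        dds = to_absolute(rel, dap_from_grid(bm.dap), depth=bm.dap.depth)
        corrected[bid] = dds
        phase[bid] = fit_phase_space(bm.inair_sizes_x, bm.inair_sizes_y)
        zp_est[bid] = estimate_peak_depth(bm.z, dds.idd1)

    # --- global fragment-halo models from frame fits ---
    if not frame_measurements:
        raise InvalidParameterError("frame measurements are required")
    by_beam: Dict[str, List[FrameMeasurement]] = {}
    for m in frame_measurements:
        by_beam.setdefault(m.beam_id, []).append(m)
    s2_z, s2_v, s2_zp = [], [], []
    i3_z, i3_v, i3_zp = [], [], []
    for bid, ms in by_beam.items():
        bm = mset.beams[bid]
        # provisional record carrying the known first component
        provisional = _provisional_record(bid, bm, corrected[bid], phase[bid],
                                          mset, zp_est[bid], eps)
        fits = fit_fragment_components(ms, provisional, seed=seed)
        zp_parent = zp_est[bid] + bm.shifter_wet
        for f in fits:
            s2_z.append(f.depth + bm.shifter_wet)
            s2_v.append(f.sigma2)
            s2_zp.append(zp_parent)
            i3_z.append(f.depth + bm.shifter_wet)
            i3_v.append(f.idd3)
            i3_zp.append(zp_parent)
    sigma_model_ref = fit_sigma2_function(s2_z, s2_v, s2_zp, seed=seed)
    idd_model_ref = fit_idd3_function(i3_z, i3_v, i3_zp, seed=seed)

    # --- assemble records ---
    beams: Dict[str, BeamRecord] = {}
    base_ps: Dict[float, PhaseSpace] = {}
    for bid, bm in mset.beams.items():
        if bm.shifter_wet == 0:
            base_ps[bm.energy] = phase[bid]
    for bid, bm in mset.beams.items():
        dds = corrected[bid]
        zp_parent = zp_est[bid] + bm.shifter_wet
        sig_model = FragmentSigmaModel(
            c1=sigma_model_ref.c1, c2=sigma_model_ref.c2,
            c3=sigma_model_ref.c3, zp=zp_parent, sigma3=eps_sigma3)
        idd_model = FragmentIddModel(
            c4=idd_model_ref.c4, c5=idd_model_ref.c5, c6=idd_model_ref.c6,
            zp=zp_parent)
        idd3_vals = idd3_curve(bm.z + bm.shifter_wet, idd_model)
        idd2_vals = decompose_fragment(dds.idd_frag, idd3_vals, eps)
        full = DepthDoseSet(z=bm.z, idd1=dds.idd1, idd_frag=dds.idd_frag,
                            idd2=idd2_vals, idd3=idd3_vals, absolute=True)
        beams[bid] = BeamRecord(
            beam_id=bid, energy=bm.energy, shifter_wet=bm.shifter_wet,
            water_range=bm.nominal_range, dds=full, phase_space=phase[bid],
            base_phase_space=base_ps.get(bm.energy, phase[bid]),
            scattering=mset.truth.scattering,
            sigma_model=sig_model, idd_model=idd_model, quality=bm.quality)
    return BeamLibrary(beams=beams, lq=mset.lq, monitor=mset.truth.monitor,
                       scattering=mset.truth.scattering,
                       stopping=mset.stopping,
                       meta={"source": "modeled-from-measurements"})


def _provisional_record(bid, bm, dds, ps, mset, zp, eps) -> BeamRecord:
    """Record with the known first component and placeholder halo models,
    used only to evaluate/subtract the first component in frame fits."""
    zp_parent = zp + bm.shifter_wet
    sig_model = FragmentSigmaModel(zp=zp_parent)
    idd_model = FragmentIddModel(zp=zp_parent)
    idd3_vals = idd3_curve(bm.z + bm.shifter_wet, idd_model)
    idd2_vals = decompose_fragment(dds.idd_frag, idd3_vals, eps)
    full = DepthDoseSet(z=bm.z, idd1=dds.idd1, idd_frag=dds.idd_frag,
                        idd2=idd2_vals, idd3=idd3_vals, absolute=True)
    return BeamRecord(
        beam_id=bid, energy=bm.energy, shifter_wet=bm.shifter_wet,
        water_range=zp, dds=full, phase_space=ps, base_phase_space=ps,
        scattering=mset.truth.scattering, sigma_model=sig_model,
        idd_model=idd_model, quality=bm.quality)


# ---------------------------------------------------------------------------
# IDNF

@dataclass
class IdnfCase:
    """One volume irradiation: its spot list and the measured center dose."""

    case_id: str
    spot_list: SpotList
    point: tuple        # (x, y, z) measurement position, z in mm water
    measured_dose: float


@dataclass
class IdnfTable:
    """Per-beam multiplicative factors on the absolute IDD."""

    factors: Dict[str, float]

    def __post_init__(self) -> None:
        for bid, f in self.factors.items():
            if not 0.9 <= f <= 1.1:
                raise InvalidParameterError(
                    f"IDNF factor for {bid} outside [0.9, 1.1]: {f}")

    def apply(self, library: BeamLibrary) -> BeamLibrary:
        """New library with each beam's absolute curves scaled by its factor."""
        beams = {}
        for bid, beam in library.beams.items():
            f = self.factors.get(bid, 1.0)
            dds = beam.dds
            new = DepthDoseSet(z=dds.z, idd1=dds.idd1 * f,
                               idd_frag=dds.idd_frag * f,
                               idd2=dds.idd2 * f, idd3=dds.idd3 * f,
                               absolute=True)
            beams[bid] = BeamRecord(
                beam_id=beam.beam_id, energy=beam.energy,
                shifter_wet=beam.shifter_wet, water_range=beam.water_range,
                dds=new, phase_space=beam.phase_space,
                base_phase_space=beam.base_phase_space,
                scattering=beam.scattering, sigma_model=beam.sigma_model,
                idd_model=beam.idd_model, quality=beam.quality)
        return BeamLibrary(beams=beams, lq=library.lq, monitor=library.monitor,
                           scattering=library.scattering,
                           stopping=library.stopping,
                           meta={**library.meta, "idnf": "applied"})


def compute_idnf(cases: Sequence[IdnfCase], library: BeamLibrary,
                 bounds: tuple = (0.9, 1.1)) -> IdnfTable:
    """Per-beam correction factors from volume-irradiation measurements.

    Solves a bounded linear least-squares problem on the relative residuals
    between calculated and measured center doses, with one factor per beam.
    Beams contributing to no case get factor 1 with a warning.
    """
    beam_ids = sorted({s.beam_id for c in cases for s in c.spot_list.spots})
    idx = {bid: i for i, bid in enumerate(beam_ids)}
    A = np.zeros((len(cases), len(beam_ids)))
    for ci, case in enumerate(cases):
        if case.measured_dose <= 0:
            raise InvalidParameterError("measured dose must be > 0")
        px, py, pz = case.point
        for bid, (xs, ys, ws) in case.spot_list.by_beam().items():
            beam = library.beams[bid]
            d1, d2, d3 = dose_components_at_points(
                beam, xs, ys, ws, [px], [py], [pz])
            A[ci, idx[bid]] = (float(d1[0] + d2[0] + d3[0])
                               / case.measured_dose)
    used = A.any(axis=0)
    factors = {bid: 1.0 for bid in library.beams}
    if used.any():
        sol = optimize.lsq_linear(A[:, used], np.ones(len(cases)),
                                  bounds=(bounds[0], bounds[1]))
        for bid, f in zip(np.array(beam_ids)[used], sol.x):
            factors[bid] = float(f)
    for bid in np.array(beam_ids)[~used]:
        log.warning("beam %s appears in no IDNF case; factor 1", bid)
    return IdnfTable(factors=factors)


# ---------------------------------------------------------------------------
# LQ survival fit

def fit_lq_survival(points: Sequence[tuple]) -> tuple:
    """LQ fit to (dose, surviving fraction) pairs: -ln SF = alpha d + beta d^2.

    No intercept (SF(0) = 1 by construction); beta is constrained
    non-negative.  Raises on fewer than three points or a single dose level.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise InvalidParameterError("need at least 3 survival points")
    d = pts[:, 0]
    sf = pts[:, 1]
    if np.any(sf <= 0) or np.any(sf > 1):
        raise InvalidParameterError("surviving fractions must be in (0, 1]")
    if len(np.unique(d)) < 2:
        raise FitFailureError("degenerate survival data: single dose level")
    y = -np.log(sf)
    A = np.stack([d, d ** 2], axis=1)
    sol = optimize.lsq_linear(A, y, bounds=([-np.inf, 0.0], [np.inf, np.inf]))
    return float(sol.x[0]), float(sol.x[1])
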