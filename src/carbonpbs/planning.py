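"""Spot placement and biological-effect optimization for SOBP fields.

A spread-out Bragg peak is built by stacking beams from the 3-mm range
ladder over the target depth interval on a 3-mm lateral spot lattice.  The
spot weights are optimized so the biological effect e_i = alpha_i d_i +
beta_i d_i^2 matches the goal E = -ln(0.1) (10% survival of the reference
cell line) at every target point, by bounded quasi-Newton (L-BFGS-B) descent
on the sum of squared effect residuals

    F(w) = sum_target (e_i - E_i)^2 + sum_OAR max(0, e_i - E_OAR)^2.

The effect is a quadratic form in the weights through the dose-averaged LQ
mixing, so the gradient is analytic.  Afterwards the plan is rescaled from
the fixed 10%-survival level to the prescription: F_scale = D_pres / d_clin
(10% survival) multiplies every weight, the physical dose and (by the
planning convention, not LQ-exactness) the reported clinical dose; the OAR
goal effect is expressed at the 10%-survival level through the same factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy import optimize

from .biology import (GOAL_EFFECT_10PCT, LqTable, clinical_dose,
                      partition_dose, photon_equivalent, rbe)
from .engine import Spot, SpotList, dose_components_at_points
from .errors import InvalidParameterError
from .library import BeamLibrary

D_CLIN_10PCT = float(clinical_dose(photon_equivalent(GOAL_EFFECT_10PCT)))


@dataclass
class PlanGoal:
    """Target points with their goal effects plus optional OAR points."""

    target_points: np.ndarray          # (n, 3) mm
    goal_effect: float = GOAL_EFFECT_10PCT
    oar_points: Optional[np.ndarray] = None
    oar_goal_effect: Optional[float] = None
    w_min: float = 0.0

    def __post_init__(self) -> None:
        self.target_points = np.atleast_2d(np.asarray(self.target_points, float))
        if self.goal_effect <= 0:
            raise InvalidParameterError("goal effect must be > 0")
        if self.oar_points is not None:
            self.oar_points = np.atleast_2d(np.asarray(self.oar_points, float))
            if self.oar_goal_effect is None:
                raise InvalidParameterError("OAR points require an OAR goal effect")


@dataclass(frozen=True)
class Prescription:
    """Clinical prescription and the derived plan scale factor."""

    d_pres: float                 # GyE
    d_oar: Optional[float] = None  # GyE
    f_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.d_pres <= 0:
            raise InvalidParameterError("prescribed dose must be > 0")


def build_sobp_plan(range_mm: float, sobp_width_mm: float, field_mm: float,
                    library: BeamLibrary, spacing: float = 3.0,
                    lateral_margin: float = 6.0,
                    initial_weight: float = 1.0) -> SpotList:
    """Uniform-weight spot list covering an SOBP target.

    Depth layers sit on the 3-mm range ladder spanning
    [range - width, range]; the lateral lattice covers the square field with
    a margin.  Raises if the requested range is outside the beam library.
    """
    lo, hi = library.range_span
    if not lo - 0.5 <= range_mm <= hi + 0.5:
        raise InvalidParameterError(
            f"range {range_mm} mm outside the library ladder [{lo}, {hi}]")
    n_layers = int(math.floor(sobp_width_mm / spacing + 1e-9)) + 1
    ranges = [range_mm - spacing * k for k in range(n_layers)]
    n_half = int(math.ceil((field_mm / 2.0 + lateral_margin) / spacing))
    lat = spacing * np.arange(-n_half, n_half + 1)
    spots: List[Spot] = []
    for r in ranges:
        beam = library.beam_for_range(r)
        for x in lat:
            for y in lat:
                spots.append(Spot(float(x), float(y), beam.beam_id,
                                  float(initial_weight)))
    return SpotList(spots=spots, f_scale=1.0)


def sobp_goal_points(range_mm: float, sobp_width_mm: float,
                     step: float = 2.0, distal_margin: float = 4.0,
                     axis_xy=(0.0, 0.0)) -> np.ndarray:
    """Central-axis goal points on a 2-mm grid within the SOBP target.

    The grid ends ``distal_margin`` upstream of the nominal range because
    the flat region physically ends at the deepest constituent Bragg peak,
    which sits one peak-offset (about 2 mm) upstream of the beam range,
    with another ripple-filter width of transition before the falloff.
    """
    zs = np.arange(range_mm - sobp_width_mm,
                   range_mm - distal_margin + 1e-9, step)
    return np.stack([np.full_like(zs, axis_xy[0]),
                     np.full_like(zs, axis_xy[1]), zs], axis=1)


# ---------------------------------------------------------------------------
# effect kernels and the optimizer

@dataclass
class EffectKernel:
    """Linear maps from layer weights to dose and LQ-weighted dose at points.

    For point i and weight group j:  d_i = (D w)_i,
    (alpha_i d_i) = (A w)_i, (beta_i d_i) = (B w)_i, so the effect is
    e_i = (A w)_i + (B w)_i (D w)_i.
    """

    D: np.ndarray
    A: np.ndarray
    B: np.ndarray
    group_ids: List[str]
    spots_per_group: np.ndarray

    def dose(self, w):
        return self.D @ w

    def effect(self, w):
        t = self.D @ w
        return self.A @ w + (self.B @ w) * t

    def lq(self, w):
        """Dose-averaged (alpha_i, beta_i) at the kernel points."""
        t = self.D @ w
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(t > 0, (self.A @ w) / np.where(t > 0, t, 1.0), np.nan)
            b = np.where(t > 0, (self.B @ w) / np.where(t > 0, t, 1.0), np.nan)
        return a, b

    def effect_jacobian(self, w):
        t = self.D @ w
        v = self.B @ w
        return self.A + v[:, None] * self.D + t[:, None] * self.B


def build_effect_kernel(spot_list: SpotList, library: BeamLibrary,
                        points, lq: Optional[LqTable] = None) -> EffectKernel:
    """Assemble per-layer kernels at evaluation points.

    Spots are grouped by beam (one weight per energy layer; the lateral
    lattice within a layer is uniform by construction).  Carbon alpha uses
    the directly scored depth curve; carbon beta and both helium
    coefficients come from the LQ tables at the beam's dose-averaged LET.
    """
    lq = lq or library.lq
    points = np.atleast_2d(np.asarray(points, dtype=float))
    px, py, pz = points[:, 0], points[:, 1], points[:, 2]
    groups = spot_list.by_beam()
    gids = sorted(groups)
    n, m = len(points), len(gids)
    D = np.zeros((n, m))
    A = np.zeros((n, m))
    B = np.zeros((n, m))
    counts = np.zeros(m)
    for j, bid in enumerate(gids):
        xs, ys, ws = groups[bid]
        beam = library.beams[bid]
        rel = ws / ws.max() if ws.max() > 0 else np.ones_like(ws)
        d1, d2, d3 = dose_components_at_points(beam, xs, ys, rel, px, py, pz)
        q = beam.quality
        r = q.interp("r", pz)
        d_c, d_frag = partition_dose(d1, d2, d3, r)
        let_c = q.interp("let_c", pz)
        let_f = q.interp("let_frag", pz)
        a_c = q.interp("alpha_c_direct", pz)
        D[:, j] = d1 + d2 + d3
        A[:, j] = a_c * d_c + lq.alpha_helium(let_f) * d_frag
        B[:, j] = lq.beta_carbon(let_c) * d_c + lq.beta_helium(let_f) * d_frag
        counts[j] = len(xs)
    return EffectKernel(D=D, A=A, B=B, group_ids=gids, spots_per_group=counts)


def objective(w, kernel: EffectKernel, goal: PlanGoal,
              oar_kernel: Optional[EffectKernel] = None) -> float:
    """Sum of squared effect residuals at the goal points (plus OAR penalty)."""
    e = kernel.effect(np.asarray(w, dtype=float))
    f = float(np.sum((e - goal.goal_effect) ** 2))
    if oar_kernel is not None and goal.oar_goal_effect is not None:
        eo = oar_kernel.effect(np.asarray(w, dtype=float))
        f += float(np.sum(np.maximum(0.0, eo - goal.oar_goal_effect) ** 2))
    return f


def _grad(w, kernel, goal, oar_kernel):
    e = kernel.effect(w)
    J = kernel.effect_jacobian(w)
    g = 2.0 * ((e - goal.goal_effect) @ J)
    if oar_kernel is not None and goal.oar_goal_effect is not None:
        eo = oar_kernel.effect(w)
        Jo = oar_kernel.effect_jacobian(w)
        g = g + 2.0 * (np.maximum(0.0, eo - goal.oar_goal_effect) @ Jo)
    return g


@dataclass
class OptimizationResult:
    spot_list: SpotList
    weights: Dict[str, float]
    effects: np.ndarray
    objective: float
    converged: bool
    n_iter: int


def optimize_weights(spot_list: SpotList, library: BeamLibrary,
                     goal: PlanGoal, lq: Optional[LqTable] = None,
                     max_iter: int = 500, ftol: float = 1e-8,
                     x0: Optional[np.ndarray] = None) -> OptimizationResult:
    """Bounded quasi-Newton (L-BFGS-B) optimization of layer weights.

    One weight per energy layer (all spots of a layer share it).  The
    gradient of the quadratic effect model is analytic.  On
    non-convergence the best iterate is returned with ``converged=False``
    and a warning in the result.
    """
    kernel = build_effect_kernel(spot_list, library, goal.target_points, lq)
    oar_kernel = None
    if goal.oar_points is not None:
        oar_kernel = build_effect_kernel(spot_list, library, goal.oar_points, lq)

    m = len(kernel.group_ids)
    if x0 is None:
        # start from the weight making the mean effect right at mean alpha
        x0 = np.full(m, 0.1)
    bounds = [(goal.w_min, None)] * m
    sol = optimize.minimize(
        lambda w: objective(w, kernel, goal, oar_kernel), x0,
        jac=lambda w: _grad(w, kernel, goal, oar_kernel),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": ftol, "gtol": 1e-12})
    w = np.maximum(sol.x, goal.w_min)
    weights = dict(zip(kernel.group_ids, w))
    groups = spot_list.by_beam()
    new_spots = []
    for s in spot_list.spots:
        ws_max = groups[s.beam_id][2].max()
        rel = s.w / ws_max if ws_max > 0 else 1.0
        new_spots.append(Spot(s.x, s.y, s.beam_id,
                              float(rel * weights[s.beam_id])))
    return OptimizationResult(
        spot_list=SpotList(new_spots, f_scale=spot_list.f_scale),
        weights=weights, effects=kernel.effect(w),
        objective=float(sol.fun), converged=bool(sol.success),
        n_iter=int(sol.nit))


# ---------------------------------------------------------------------------
# prescription scaling

def scale_factor(d_pres: float, d_clin_10pct: float = D_CLIN_10PCT) -> float:
    """F_scale = prescribed clinical dose over the fixed 10%-survival level."""
    if d_clin_10pct <= 0:
        raise InvalidParameterError("d_clin at 10% survival must be > 0")
    return d_pres / d_clin_10pct


def apply_scale(plan: SpotList, f_scale: float) -> SpotList:
    """Scale every spot weight by F_scale and record it in the plan header."""
    return plan.scaled(f_scale)


def oar_goal_effect(d_oar: float, f_scale: float,
                    lq: Optional[LqTable] = None) -> float:
    """OAR goal effect at the 10%-survival optimization level.

    The OAR clinical-dose constraint is mapped back through the clinical
    factor and F_scale to a photon-equivalent dose, then through the photon
    LQ to an effect: E = aX u + bX u^2 with u = D_OAR / (1.46 F_scale).
    """
    if f_scale <= 0:
        raise InvalidParameterError("F_scale must be > 0")
    ax = lq.alpha_x if lq is not None else 0.33
    bx = lq.beta_x if lq is not None else 0.06
    cf = lq.clinical_factor if lq is not None else 1.46
    u = d_oar / (cf * f_scale)
    return ax * u + bx * u ** 2


# ---------------------------------------------------------------------------
# depth profiles

def depth_profile(spot_list: SpotList, library: BeamLibrary, depths,
                  axis_xy=(0.0, 0.0), lq: Optional[LqTable] = None) -> dict:
    """Central-axis profile of physical/biological/clinical dose and RBE.

    The LQ effect is evaluated at the 10%-survival optimization level
    (weights divided by the plan's scale factor); physical, biological and
    clinical dose are then scaled linearly by the factor, following the
    planning convention that prescription scaling does not change the RBE.
    ``effect`` and the LQ coefficients are reported at the 10% level.
    """
    lq = lq or library.lq
    depths = np.asarray(depths, dtype=float)
    pts = np.stack([np.full_like(depths, axis_xy[0]),
                    np.full_like(depths, axis_xy[1]), depths], axis=1)
    kernel = build_effect_kernel(spot_list, library, pts, lq)
    groups = spot_list.by_beam()
    f = spot_list.f_scale
    w10 = np.array([groups[g][2].max() for g in kernel.group_ids]) / f
    d10 = kernel.dose(w10)
    e = kernel.effect(w10)
    alpha, beta = kernel.lq(w10)
    d_bio = f * photon_equivalent(e, lq)
    d_clin = clinical_dose(d_bio, lq)
    d = f * d10
    return {
        "z": depths, "dose": d, "alpha": alpha, "beta": beta, "effect": e,
        "d_bio": d_bio, "d_clin": d_clin, "rbe": rbe(d_clin, d),
    }
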