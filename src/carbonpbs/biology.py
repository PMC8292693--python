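"""Mixed-field linear-quadratic model and photon-equivalent (clinical) dose.

Cell survival at a voxel is S = exp(-alpha d - beta d^2).  In a mixed field
the LQ coefficients are dose-averaged over the contributing beams, with the
second Gaussian component split between carbon isotopes (e.g. ^11C) and
lighter fragments by the depth-dependent ratio R(z):

    d^(C)    = d^(1) + (1 - R) d^(2)        carbon LQ parameters apply
    d^(frag) = R d^(2) + d^(3)              helium LQ parameters apply

Carbon alpha comes from a directly scored dose-averaged alpha(z) (it varies
steeply across the broad LET spectrum near the peak); the remaining LQ
coefficients are looked up in LET tables at the beam's dose-averaged LET.
The biological dose d_bio is the photon dose producing the same effect
(closed-form inverse of the photon LQ), and the clinical dose is a fixed
1.46 times d_bio; the clinical RBE is d_clin / d_phys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .errors import InvalidParameterError

CLINICAL_FACTOR = 1.46
ALPHA_X = 0.33  # Gy^-1, photon LQ
BETA_X = 0.06   # Gy^-2, photon LQ
GOAL_EFFECT_10PCT = -math.log(0.1)


@dataclass
class LqTable:
    """LET-dependent LQ coefficients for carbon and helium plus photon constants."""

    let_grid: np.ndarray
    alpha_c: np.ndarray
    beta_c: np.ndarray
    alpha_he: np.ndarray
    beta_he: np.ndarray
    alpha_x: float = ALPHA_X
    beta_x: float = BETA_X
    clinical_factor: float = CLINICAL_FACTOR

    def __post_init__(self) -> None:
        self.let_grid = np.asarray(self.let_grid, dtype=float)
        for name in ("alpha_c", "beta_c", "alpha_he", "beta_he"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != self.let_grid.shape:
                raise InvalidParameterError(f"LqTable.{name} shape mismatch")
            if np.any(v < 0):
                raise InvalidParameterError(f"LqTable.{name} must be >= 0")
        if np.any(np.diff(self.let_grid) <= 0):
            raise InvalidParameterError("LET grid must be strictly increasing")

    def _interp(self, vals, let):
        # linear in LET; clamped to the table endpoints outside the grid
        return np.interp(np.asarray(let, dtype=float), self.let_grid, vals)

    def alpha_carbon(self, let):
        return self._interp(self.alpha_c, let)

    def beta_carbon(self, let):
        return self._interp(self.beta_c, let)

    def alpha_helium(self, let):
        return self._interp(self.alpha_he, let)

    def beta_helium(self, let):
        return self._interp(self.beta_he, let)


def default_lq_table() -> LqTable:
    """Synthetic stand-in LQ(LET) curves.

    The published curves are not tabulated, so these piecewise-linear
    stand-ins reproduce only their qualitative shape: carbon alpha rises
    with LET to a plateau near 150-200 keV/um, helium analogously but lower;
    beta declines slowly.  Replace with facility tables for real use.
    """
    let = np.array([5.0, 10.0, 20.0, 40.0, 70.0, 100.0, 150.0, 200.0, 300.0])
    return LqTable(
        let_grid=let,
        alpha_c=np.array([0.12, 0.16, 0.24, 0.40, 0.60, 0.74, 0.86, 0.90, 0.90]),
        beta_c=np.array([0.060, 0.060, 0.058, 0.054, 0.048, 0.042, 0.036,
                         0.032, 0.032]),
        alpha_he=np.array([0.10, 0.12, 0.17, 0.28, 0.42, 0.52, 0.60, 0.62, 0.62]),
        beta_he=np.array([0.050, 0.050, 0.050, 0.048, 0.046, 0.044, 0.042,
                          0.040, 0.040]),
    )


@dataclass
class RadiationQuality:
    """Depth curves of radiation quality for one beam.

    LET curves in keV/um, the directly scored dose-averaged carbon alpha in
    Gy^-1, and the fragment ratio R(z) in [0, 1] (share of the second
    component's dose carried by Z <= 5 fragments rather than carbon isotopes).
    """

    z: np.ndarray
    let_c: np.ndarray
    let_frag: np.ndarray
    alpha_c_direct: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        for name in ("let_c", "let_frag", "alpha_c_direct", "r"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != self.z.shape:
                raise InvalidParameterError(f"RadiationQuality.{name} shape mismatch")
        if np.any(self.let_c <= 0) or np.any(self.let_frag <= 0):
            raise InvalidParameterError("LET curves must be positive")
        if np.any((self.r < 0) | (self.r > 1)):
            raise InvalidParameterError("R(z) must lie in [0, 1]")

    def interp(self, name: str, z):
        vals = getattr(self, name)
        return np.interp(np.asarray(z, dtype=float), self.z, vals)


@dataclass(frozen=True)
class EventRecord:
    """One scored transport event: species charge, energy, energy deposit."""

    charge_z: int
    energy: float        # MeV per nucleon
    delta_e: float       # MeV deposited
    is_primary_12c: bool = False

    def __post_init__(self) -> None:
        if self.delta_e < 0:
            raise InvalidParameterError("energy deposit must be >= 0")


@dataclass
class EventList:
    """Columnar container of event records for vectorized scoring."""

    charge_z: np.ndarray
    energy: np.ndarray
    delta_e: np.ndarray
    is_primary_12c: np.ndarray

    @classmethod
    def from_records(cls, records: Iterable[EventRecord]) -> "EventList":
        recs = list(records)
        return cls(
            charge_z=np.array([r.charge_z for r in recs], dtype=int),
            energy=np.array([r.energy for r in recs], dtype=float),
            delta_e=np.array([r.delta_e for r in recs], dtype=float),
            is_primary_12c=np.array([r.is_primary_12c for r in recs], dtype=bool),
        )

    def __len__(self) -> int:
        return len(self.delta_e)


def _as_event_list(events) -> EventList:
    if isinstance(events, EventList):
        return events
    return EventList.from_records(events)


def event_stopping_power(events, sp) -> np.ndarray:
    """Per-event stopping power (MeV/mm), scaled from the carbon curve.

    For a given energy per nucleon the stopping power scales approximately
    with the squared charge, so non-carbon species use (Z/6)^2 times the
    carbon S(E).  For Z = 6 this is the carbon table itself.
    """
    ev = _as_event_list(events)
    return (ev.charge_z / 6.0) ** 2 * sp.s_of_e(ev.energy)


def carbon_ratio_from_events(events) -> float:
    """Fragment ratio R: Z<=5 deposit over all non-primary-^12C deposit.

    Returns NaN when no non-primary deposit exists.
    """
    ev = _as_event_list(events)
    secondary = ~ev.is_primary_12c
    denom = float(ev.delta_e[secondary].sum())
    if denom <= 0:
        return float("nan")
    num = float(ev.delta_e[secondary & (ev.charge_z <= 5)].sum())
    return num / denom


def letd_from_events(events, species: str, sp) -> float:
    """Dose-averaged LET (keV/um): deposit-weighted mean stopping power.

    ``species`` selects the scored events: "carbon" keeps Z = 6, "fragment"
    keeps Z != 6.  Returns NaN for an empty filtered set.  (1 MeV/mm of
    stopping power in water equals 1 keV/um numerically.)
    """
    ev = _as_event_list(events)
    if species == "carbon":
        sel = ev.charge_z == 6
    elif species == "fragment":
        sel = ev.charge_z != 6
    else:
        raise InvalidParameterError("species must be 'carbon' or 'fragment'")
    w = ev.delta_e[sel]
    if w.sum() <= 0:
        return float("nan")
    s = event_stopping_power(EventList(ev.charge_z[sel], ev.energy[sel],
                                       w, ev.is_primary_12c[sel]), sp)
    return float(np.sum(s * w) / np.sum(w))


def alpha_from_events(events, alpha_of_let, sp) -> float:
    """Dose-averaged carbon alpha: deposit-weighted mean of alpha(S(E_k)).

    Only Z = 6 events are scored; returns NaN when none are present.
    """
    ev = _as_event_list(events)
    sel = ev.charge_z == 6
    w = ev.delta_e[sel]
    if w.sum() <= 0:
        return float("nan")
    s = sp.s_of_e(ev.energy[sel])
    return float(np.sum(np.asarray(alpha_of_let(s)) * w) / np.sum(w))


def partition_dose(d1, d2, d3, r):
    """Split triple-Gaussian component doses into carbon and fragment shares.

    d^(C) = d^(1) + (1 - R) d^(2);  d^(frag) = R d^(2) + d^(3).  The shares
    sum to the total dose by construction.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    d3 = np.asarray(d3, dtype=float)
    r = np.asarray(r, dtype=float)
    d_c = d1 + (1.0 - r) * d2
    d_frag = r * d2 + d3
    return d_c, d_frag


def mix_lq(alpha_j, beta_j, dose_j, w_j=None, beta_mode: str = "linear"):
    """Dose-averaged LQ coefficients over per-beam contributions.

    alpha_i = sum_j alpha_j d_j w_j / d_i and analogously for beta.  With
    ``beta_mode='sqrt'`` the square roots of beta are dose-averaged instead
    (a convention used by some mixed-field formulations).  Returns
    (alpha, beta); NaNs when the total dose is zero.
    """
    alpha_j = np.asarray(alpha_j, dtype=float)
    beta_j = np.asarray(beta_j, dtype=float)
    dose_j = np.asarray(dose_j, dtype=float)
    w = np.ones_like(dose_j) if w_j is None else np.asarray(w_j, dtype=float)
    d = dose_j * w
    total = d.sum()
    if total <= 0:
        return float("nan"), float("nan")
    alpha = float(np.sum(alpha_j * d) / total)
    if beta_mode == "linear":
        beta = float(np.sum(beta_j * d) / total)
    elif beta_mode == "sqrt":
        beta = float(np.sum(np.sqrt(beta_j) * d) / total) ** 2
    else:
        raise InvalidParameterError("beta_mode must be 'linear' or 'sqrt'")
    return alpha, beta


def effect(alpha, beta, dose):
    """Biological effect e = alpha d + beta d^2."""
    dose = np.asarray(dose, dtype=float)
    return np.asarray(alpha) * dose + np.asarray(beta) * dose ** 2


def survival(e):
    """Surviving fraction S = exp(-e)."""
    return np.exp(-np.asarray(e, dtype=float))


def dose_for_effect(alpha: float, beta: float, e: float) -> float:
    """Physical dose producing effect e under LQ coefficients (alpha, beta)."""
    if e < 0:
        raise InvalidParameterError("effect must be >= 0")
    if beta <= 0:
        if alpha <= 0:
            raise InvalidParameterError("alpha must be > 0 when beta = 0")
        return e / alpha
    return (math.sqrt(alpha ** 2 + 4.0 * beta * e) - alpha) / (2.0 * beta)


def photon_equivalent(e, lq: Optional[LqTable] = None):
    """Biological dose d_bio (GyE): photon dose with the same effect.

    Closed-form inverse of the photon LQ:
    d_bio = (sqrt(alpha_X^2 + 4 beta_X e) - alpha_X) / (2 beta_X).
    """
    ax = lq.alpha_x if lq is not None else ALPHA_X
    bx = lq.beta_x if lq is not None else BETA_X
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise InvalidParameterError("effect must be >= 0")
    return (np.sqrt(ax ** 2 + 4.0 * bx * e) - ax) / (2.0 * bx)


def clinical_dose(d_bio, lq: Optional[LqTable] = None):
    """Clinical dose: 1.46 times the photon-equivalent dose."""
    f = lq.clinical_factor if lq is not None else CLINICAL_FACTOR
    return f * np.asarray(d_bio, dtype=float)


def rbe(d_clin, d_phys):
    """Clinical RBE = d_clin / d_phys; NaN where the physical dose is zero."""
    d_clin = np.asarray(d_clin, dtype=float)
    d_phys = np.asarray(d_phys, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(d_phys > 0, d_clin / np.where(d_phys > 0, d_phys, 1.0),
                       np.nan)
    return out


@dataclass
class BioGrid:
    """Per-voxel biological quantities derived from (alpha, beta, dose)."""

    alpha: np.ndarray
    beta: np.ndarray
    e: np.ndarray
    s: np.ndarray
    d_bio: np.ndarray
    d_clin: np.ndarray
    rbe_clin: np.ndarray

    @classmethod
    def from_lq(cls, alpha, beta, dose, lq: Optional[LqTable] = None) -> "BioGrid":
        e = effect(alpha, beta, dose)
        d_bio = photon_equivalent(e, lq)
        d_clin = clinical_dose(d_bio, lq)
        return cls(alpha=np.asarray(alpha, dtype=float),
                   beta=np.asarray(beta, dtype=float),
                   e=np.asarray(e, dtype=float),
                   s=survival(e),
                   d_bio=np.asarray(d_bio, dtype=float),
                   d_clin=np.asarray(d_clin, dtype=float),
                   rbe_clin=rbe(d_clin, dose))
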