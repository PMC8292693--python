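"""Synthetic stand-in for Monte Carlo scoring and facility measurements.

Everything the beam-modeling chain normally obtains from transport
simulation and dosimetry is generated here from a closed-form truth model,
so the whole package is testable without external data:

* a power-law range-energy relation R = k E^p (p = 1.795, calibrated so a
  430 MeV/n beam has a 300 mm water range and a 140 MeV/n beam about 40 mm),
  giving an analytic stopping-power table;
* pristine Bragg curves from the attenuated-fluence/straggled-stopping-power
  model, with the truth attenuation half-length lambda = 150 mm and a
  deliberately wrong raw-scoring value lambda = 170 mm so the correction
  step of the modeling chain has something real to do;
* fragment-halo curves built from the same analytic forms the model fits
  (saturating-exponential IDD3, hyperbolic sigma2, fixed sigma3 = 25 mm);
* chamber-convention curves including the 120-mm-diameter chamber's
  detection efficiency for the wide third component;
* in-air beam sizes at three planes, frame-pattern center doses, DAP
  calibrations, and depth-sampled event lists for LET/alpha scoring.

All generators are deterministic under a fixed seed.  Quantities the source
facility never published (LQ tables, straggling, event mixtures, the phase
spaces) are labeled stand-ins and chosen at physically plausible scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import lateral
from .biology import EventList, LqTable, RadiationQuality, default_lq_table
from .depthdose import (DEFAULT_Z_GRID, DapCalibration, DepthDoseSet,
                        PristineBeamParams, StoppingPowerCurve,
                        detection_efficiency, pristine_idd)
from .engine import BeamRecord
from .errors import InvalidParameterError
from .lateral import (AxisMoments, FragmentIddModel, FragmentSigmaModel,
                      PhaseSpace, ScatteringParams, scattering_increment)
from .library import BeamLibrary
from .units import MonitorSpec, monitor_gain, particles_per_mu

MEV_PER_MM_TO_GY_MM2 = 1.602e-7  # (MeV/mm) * particles -> Gy mm^2, water
CHAMBER_RADIUS_MM = 60.0


@dataclass
class SyntheticTruth:
    """Full generating parameter set of the synthetic facility.

    Regeneration with the same seed is bit-identical.  Printed facility
    constants (lambda values, scattering C, fragment constants, sigma3,
    chamber radius) double as the defaults here; the rest are stand-ins.
    """

    # range-energy power law R = k E^p (mm, MeV/n)
    range_k: float = 300.0 / 430.0 ** 1.795
    range_p: float = 1.795
    # fluence attenuation half-lengths (mm): truth and raw-scoring values
    lam_true: float = 150.0
    lam_raw: float = 170.0
    # straggling scaling sigma = strag_a * R0^strag_b (mm); the floor
    # emulates the ripple filter that broadens the pristine peaks so the
    # 3-mm range ladder stacks without ripple
    strag_a: float = 0.012
    strag_b: float = 0.935
    ripple_sigma: float = 1.8
    # fragment halo constants
    c1: float = 5.0
    c2: float = 30.0
    c3: float = 0.006
    sigma3: float = 25.0
    c4: float = 21.0
    c5: float = 500.0
    c6: float = 1.5
    # second-component depth curve (stand-in shape)
    frag2_amp: float = 50.0      # Gy mm^2/MU saturation
    frag2_lam: float = 150.0     # mm build-up half-length
    frag2_tail: float = 25.0     # mm distal decay length
    # optics stand-ins
    spot_sigma_a: float = 2.5    # mm, isocenter spot size = a + b / range
    spot_sigma_b: float = 250.0  # mm^2
    angular_var: float = 2.25e-6  # rad^2
    waist_offset_y: float = 100.0  # mm upstream waist of the y axis
    shifter_pos: float = -400.0  # mm, range-shifter plane
    scattering: ScatteringParams = field(default_factory=ScatteringParams)
    monitor: MonitorSpec = field(default_factory=MonitorSpec)
    # event-mixture stand-in
    frag_c11_share: float = 0.3  # share of secondary deposit from carbon isotopes
    event_energy_spread: float = 0.2
    seed: int = 0

    def range_of_energy(self, e) -> np.ndarray:
        return self.range_k * np.asarray(e, dtype=float) ** self.range_p

    def energy_of_range(self, r) -> np.ndarray:
        return (np.asarray(r, dtype=float) / self.range_k) ** (1.0 / self.range_p)

    @property
    def epsilon(self) -> float:
        return detection_efficiency(CHAMBER_RADIUS_MM, self.sigma3)


def make_stopping_power(truth: SyntheticTruth,
                        r_grid: Optional[np.ndarray] = None,
                        e_grid: Optional[np.ndarray] = None) -> StoppingPowerCurve:
    """Analytic stopping-power table from the power-law range-energy relation.

    With R = k E^p the ion's total stopping power is S = 12 E / (p R) in
    MeV/mm (E per nucleon, 12 nucleons), i.e. S(r) scales as r^(1/p - 1).
    The integral of S over residual range 0..R recovers E exactly.
    """
    k, p = truth.range_k, truth.range_p
    if not 1.0 < p < 2.0:
        raise InvalidParameterError("range-energy exponent must be in (1, 2)")
    if r_grid is None:
        r_grid = np.concatenate([np.arange(0.05, 5.0, 0.05),
                                 np.arange(5.0, 351.0, 0.5)])
    if e_grid is None:
        e_grid = np.linspace(5.0, 500.0, 400)

    def fn_r(r):
        e = (np.asarray(r, dtype=float) / k) ** (1.0 / p)
        return 12.0 * e / (p * np.asarray(r, dtype=float))

    def fn_e(e):
        e = np.asarray(e, dtype=float)
        return 12.0 * e / (p * truth.range_of_energy(e))

    return StoppingPowerCurve(r_grid=r_grid, s_r=fn_r(r_grid),
                              e_grid=e_grid, s_e=fn_e(e_grid),
                              fn_r=fn_r, fn_e=fn_e)


def air_mass_stopping_power(energy: float, truth: SyntheticTruth) -> float:
    """Stand-in mass stopping power of carbon in air, MeV cm^2/g.

    Air and water mass stopping powers agree to a few percent for fast ions,
    so the water value (S[MeV/mm] * 10 / 1 g/cm^3) is used.
    """
    sp = make_stopping_power(truth)
    return 10.0 * float(sp.s_of_e(energy))


def particles_per_mu_for_energy(energy: float, truth: SyntheticTruth) -> float:
    g = monitor_gain(air_mass_stopping_power(energy, truth), truth.monitor)
    return particles_per_mu(g, truth.monitor)


def _base_phase_space(truth: SyntheticTruth, water_range: float) -> PhaseSpace:
    s_iso = truth.spot_sigma_a + truth.spot_sigma_b / water_range
    s22 = truth.angular_var
    x = AxisMoments(s_iso ** 2, 0.0, s22)
    # y waist sits upstream of the isocenter
    zw = truth.waist_offset_y
    y = AxisMoments(s_iso ** 2 + s22 * zw ** 2, s22 * zw, s22)
    return PhaseSpace(x, y)


def _shifted_phase_space(truth: SyntheticTruth, base: PhaseSpace,
                         range_noshift: float, wet: float) -> PhaseSpace:
    """Phase space at the isocenter after a thin shifter at ``shifter_pos``."""
    if wet <= 0:
        return base
    dth2 = scattering_increment(truth.scattering, range_noshift,
                                range_noshift - wet)
    L = -truth.shifter_pos

    def axis(a: AxisMoments) -> AxisMoments:
        # drift back to the shifter plane, add the angular kick, drift forward
        s11 = a.s11 - 2.0 * a.s12 * L + a.s22 * L ** 2
        s12 = a.s12 - a.s22 * L
        s22 = a.s22 + dth2
        s12f = s12 + s22 * L
        s11f = s11 + 2.0 * s12 * L + s22 * L ** 2
        return AxisMoments(max(s11f, 0.0), s12f, s22)

    return PhaseSpace(axis(base.x), axis(base.y))


def _idd2_truth(z, truth: SyntheticTruth, zp_parent: float, shift: float) -> np.ndarray:
    """Stand-in second-component depth curve (build-up, distal tail)."""
    zz = np.asarray(z, dtype=float) + shift
    build = truth.frag2_amp * (1.0 - np.power(2.0, -zz / truth.frag2_lam))
    peak = truth.frag2_amp * (1.0 - 2.0 ** (-zp_parent / truth.frag2_lam))
    tail = peak * np.exp(-np.maximum(zz - zp_parent, 0.0) / truth.frag2_tail)
    return np.where(zz <= zp_parent, np.maximum(build, 0.0), tail)


def quality_curves(truth: SyntheticTruth, sp: StoppingPowerCurve,
                   water_range: float, shifter_wet: float,
                   lq: LqTable, z: Optional[np.ndarray] = None) -> RadiationQuality:
    """Smooth stand-in radiation-quality curves for one beam."""
    if z is None:
        z = np.arange(0.0, 350.0 + 1e-9, 2.0)
    rr = np.maximum(water_range - z, 0.5)
    let_c = sp.s_of_r(rr)  # MeV/mm == keV/um in water
    let_frag = 3.0 + 10.0 * (1.0 - np.exp(-(z + shifter_wet) / 200.0))
    r = np.clip(0.65 + 0.3 * (1.0 - np.exp(-(z + shifter_wet) / 150.0)),
                0.0, 0.95)
    alpha_c = lq.alpha_carbon(let_c)
    return RadiationQuality(z=z, let_c=let_c, let_frag=let_frag,
                            alpha_c_direct=alpha_c, r=r)


@dataclass
class BeamMeasurements:
    """Raw synthetic scoring and dosimetry for one beam, pre-modeling."""

    beam_id: str
    energy: float
    shifter_wet: float
    nominal_range: float          # design water range (3-mm ladder), mm
    z: np.ndarray
    raw_idd_12c: np.ndarray       # scored with the raw (wrong) lambda
    raw_idd_frag: np.ndarray      # chamber-convention fragment curve, raw lambda
    chamber_idd: np.ndarray       # measured total (absolute Gy mm^2/MU scale)
    dap: DapCalibration
    inair_sizes_x: tuple          # sigma at z = -200, 0, +200 mm
    inair_sizes_y: tuple
    quality: RadiationQuality


@dataclass
class MeasurementSet:
    """Everything the modeling chain consumes, for a whole beam ladder."""

    truth: SyntheticTruth
    stopping: StoppingPowerCurve
    lq: LqTable
    beams: Dict[str, BeamMeasurements]
    lam_raw: float


def _peak_depth(z, y) -> float:
    """Quadratic refinement of the curve maximum."""
    i = int(np.argmax(y))
    if 0 < i < len(z) - 1:
        den = 2.0 * (y[i - 1] - 2 * y[i] + y[i + 1])
        if den != 0:
            return float(z[i] + 0.25 * (y[i - 1] - y[i + 1])
                         * (z[i + 1] - z[i - 1]) / den)
    return float(z[i])


def _truth_curves(truth: SyntheticTruth, sp: StoppingPowerCurve,
                  energy: float, wet: float, z: np.ndarray):
    """Absolute truth IDD curves (idd1, idd2, idd3) for one beam.

    The fragment models are anchored at the parent beam's Bragg-peak depth,
    i.e. the depth of the dose maximum (slightly upstream of the mean range
    because the stopping power rises toward the end of range).
    """
    range_noshift = float(truth.range_of_energy(energy))
    r0 = range_noshift - wet
    strag = max(truth.strag_a * range_noshift ** truth.strag_b,
                truth.ripple_sigma)
    params = PristineBeamParams(R0=r0, lam=truth.lam_true,
                                lam_prime=truth.lam_true,
                                sigma_strag=strag,
                                phi0=2.0 ** (-wet / truth.lam_true))
    k_mu = particles_per_mu_for_energy(energy, truth)
    idd1 = k_mu * MEV_PER_MM_TO_GY_MM2 * pristine_idd(z, params, sp)
    zp_parent = _peak_depth(z, idd1) + wet
    idd3_model = FragmentIddModel(c4=truth.c4, c5=truth.c5, c6=truth.c6,
                                  zp=zp_parent)
    idd3 = lateral.idd3_with_rs(z, wet, idd3_model)
    idd2 = _idd2_truth(z, truth, zp_parent, wet)
    return idd1, idd2, idd3, params, zp_parent


def make_beam_library(truth: Optional[SyntheticTruth] = None,
                      energies: Optional[Sequence[float]] = None,
                      shifters: Optional[Sequence[float]] = None,
                      z_grid: Optional[np.ndarray] = None,
                      noise: float = 0.0,
                      seed: Optional[int] = None):
    """Generate the truth beam library plus its raw synthetic measurements.

    By default 12 accelerator energies cover water ranges 300 down to 36 mm
    in 24-mm steps and binary shifters 0..21 mm fill the 3-mm range ladder
    in between.  Returns ``(BeamLibrary, MeasurementSet)``; the library holds
    the truth beams, the measurement set is what the modeling chain sees.
    ``noise`` adds multiplicative Gaussian noise of that relative magnitude
    to measured curves and doses.
    """
    truth = truth or SyntheticTruth()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    sp = make_stopping_power(truth)
    lq = default_lq_table()
    if energies is None:
        ranges = np.arange(300.0, 35.0, -24.0)
        energies = [float(truth.energy_of_range(r)) for r in ranges]
    if shifters is None:
        shifters = np.arange(0.0, 22.0, 3.0)
    z = DEFAULT_Z_GRID.copy() if z_grid is None else np.asarray(z_grid, float)

    beams: Dict[str, BeamRecord] = {}
    measurements: Dict[str, BeamMeasurements] = {}
    eps = truth.epsilon

    for energy in energies:
        range_noshift = float(truth.range_of_energy(energy))
        base_ps = _base_phase_space(truth, range_noshift)
        for wet in shifters:
            wet = float(wet)
            r0 = range_noshift - wet
            if r0 < 10.0:
                continue
            bid = f"E{energy:.1f}_L{wet:g}"
            idd1, idd2, idd3, params, zp_parent = _truth_curves(
                truth, sp, energy, wet, z)
            chamber = idd1 + idd2 + eps * idd3

            ps = _shifted_phase_space(truth, base_ps, range_noshift, wet)
            sig_model = FragmentSigmaModel(c1=truth.c1, c2=truth.c2,
                                           c3=truth.c3, zp=zp_parent,
                                           sigma3=truth.sigma3)
            idd_model = FragmentIddModel(c4=truth.c4, c5=truth.c5,
                                         c6=truth.c6, zp=zp_parent)
            qual = quality_curves(truth, sp, r0, wet, lq)
            dds = DepthDoseSet(z=z, idd1=idd1,
                               idd_frag=idd2 + eps * idd3,
                               idd2=idd2, idd3=idd3, absolute=True)
            beams[bid] = BeamRecord(
                beam_id=bid, energy=energy, shifter_wet=wet,
                water_range=r0, dds=dds, phase_space=ps,
                base_phase_space=base_ps, scattering=truth.scattering,
                sigma_model=sig_model, idd_model=idd_model, quality=qual)

            # ---- raw measurements for the modeling chain ----
            raw_params = PristineBeamParams(
                R0=r0, lam=truth.lam_raw, lam_prime=truth.lam_raw,
                sigma_strag=params.sigma_strag,
                phi0=2.0 ** (-wet / truth.lam_raw))
            k_mu = particles_per_mu_for_energy(energy, truth)
            raw_12c = k_mu * MEV_PER_MM_TO_GY_MM2 * pristine_idd(z, raw_params, sp)
            raw_frag = (idd2 + eps * idd3) * (truth.lam_true / truth.lam_raw)
            chamber_meas = chamber.copy()
            if noise > 0:
                chamber_meas = chamber_meas * (1.0 + noise * rng.standard_normal(len(z)))

            q_spot = 0.05
            delta = 3.0
            d20 = float(np.interp(20.0, z, chamber))
            dap = DapCalibration(
                d_meas=d20 * q_spot / delta ** 2
                * (1.0 + noise * rng.standard_normal()) if noise > 0
                else d20 * q_spot / delta ** 2,
                spacing_delta=delta, q_per_spot=q_spot, depth=20.0)

            sizes = {}
            for ax_name, ax in (("x", ps.x), ("y", ps.y)):
                vals = []
                for plane in (-200.0, 0.0, 200.0):
                    s2 = ax.s11 + 2.0 * ax.s12 * plane + ax.s22 * plane ** 2
                    s = math.sqrt(max(s2, 0.0))
                    if noise > 0:
                        s *= 1.0 + noise * rng.standard_normal()
                    vals.append(s)
                sizes[ax_name] = tuple(vals)

            measurements[bid] = BeamMeasurements(
                beam_id=bid, energy=energy, shifter_wet=wet,
                nominal_range=r0, z=z,
                raw_idd_12c=raw_12c, raw_idd_frag=raw_frag,
                chamber_idd=chamber_meas, dap=dap,
                inair_sizes_x=sizes["x"], inair_sizes_y=sizes["y"],
                quality=qual)

    library = BeamLibrary(beams=beams, lq=lq, monitor=truth.monitor,
                          scattering=truth.scattering, stopping=sp,
                          meta={"source": "synthetic-truth", "seed": truth.seed})
    mset = MeasurementSet(truth=truth, stopping=sp, lq=lq,
                          beams=measurements, lam_raw=truth.lam_raw)
    return library, mset


# ---------------------------------------------------------------------------
# event lists for LET / alpha scoring

_FRAG_SPECIES = np.array([1, 2, 3, 4, 5])
_FRAG_SHARES = np.array([0.25, 0.20, 0.20, 0.20, 0.15])


def event_mixture(truth: SyntheticTruth, water_range: float, z: float):
    """Species probabilities and mean energies of the event stand-in at depth z.

    Returns (charges, probabilities, mean energies per nucleon, primary flags).
    The primary share follows the attenuated fluence times the straggled
    survival past the peak; secondaries split between carbon isotopes and
    Z = 1..5 fragments by ``frag_c11_share``.
    """
    strag = max(truth.strag_a * water_range ** truth.strag_b,
                truth.ripple_sigma)
    surv = 0.5 * math.erfc((z - water_range) / (math.sqrt(2.0) * strag))
    p_prim = 2.0 ** (-z / truth.lam_true) * surv
    p_sec = 1.0 - p_prim
    e_prim = float(truth.energy_of_range(max(water_range - z, 0.5)))
    charges = np.concatenate([[6], [6], _FRAG_SPECIES])
    primary = np.array([True] + [False] * 6)
    probs = np.concatenate([
        [p_prim], [p_sec * truth.frag_c11_share],
        p_sec * (1.0 - truth.frag_c11_share) * _FRAG_SHARES])
    energies = np.concatenate([
        [e_prim], [0.9 * e_prim],
        np.clip(e_prim * np.array([1.3, 1.2, 1.1, 1.0, 0.9]), 5.0, 500.0)])
    return charges, probs, energies, primary


def make_events(truth: SyntheticTruth, sp: StoppingPowerCurve,
                water_range: float, z: float, n: int,
                seed: int = 0) -> EventList:
    """Sample an event list (species, energy, deposit) at one depth.

    Deposits are stopping power times a 1-mm step; energies scatter
    uniformly by +-``event_energy_spread`` around the species mean.
    Deterministic under a fixed seed.
    """
    if n < 1:
        raise InvalidParameterError("need at least one event")
    rng = np.random.default_rng(seed)
    charges, probs, energies, primary = event_mixture(truth, water_range, z)
    probs = probs / probs.sum()
    idx = rng.choice(len(charges), size=n, p=probs)
    spread = truth.event_energy_spread
    e = energies[idx] * (1.0 + spread * (2.0 * rng.random(n) - 1.0))
    e = np.clip(e, 1.0, 600.0)
    zq = charges[idx]
    de = (zq / 6.0) ** 2 * sp.s_of_e(e) * 1.0
    return EventList(charge_z=zq, energy=e, delta_e=de,
                     is_primary_12c=primary[idx])
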