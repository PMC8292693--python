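"""Monitor-unit definition and particle-number calibration.

The scanning nozzle counts delivered beam with a parallel-plate ionization
monitor.  One monitor unit (MU) is defined as a fixed collected charge
(25 nC by default).  The chain from physics to delivered particle number is

    G = (S/rho) * d * g * 1e6 / W        ion pairs per incident ion
    K = Q_MU / (G * e)                   particles per MU

where S/rho is the mass stopping power of the ion in air (MeV cm^2/g), d the
air density (g/cm^3), g the monitor air gap (cm), W the mean energy per ion
pair (eV), Q_MU the charge defining one MU (nC, converted to C) and e the
elementary charge (C).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidParameterError

ELEMENTARY_CHARGE = 1.602e-19  # C


@dataclass(frozen=True)
class MonitorSpec:
    """Geometry and calibration constants of the ionization dose monitor.

    Parameters
    ----------
    gap_g : float
        Electrode air gap in cm.
    w_value : float
        Mean energy spent per ion pair in air, eV.
    air_density_d : float
        Air mass density in g/cm^3.
    charge_per_mu : float
        Collected charge defining one MU, in nC.
    elementary_charge : float
        Elementary charge in C.
    """

    gap_g: float = 1.0
    w_value: float = 35.1
    air_density_d: float = 1.205e-3
    charge_per_mu: float = 25.0
    elementary_charge: float = ELEMENTARY_CHARGE

    def __post_init__(self) -> None:
        for name in ("gap_g", "w_value", "air_density_d", "charge_per_mu",
                     "elementary_charge"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"MonitorSpec.{name} must be > 0")


def monitor_gain(mass_stopping_power_air: float, spec: MonitorSpec) -> float:
    """Ion pairs generated in the monitor per incident particle.

    ``mass_stopping_power_air`` is the ion's mass stopping power in air in
    MeV cm^2/g.  The 1e6 factor converts MeV to eV.
    """
    if mass_stopping_power_air <= 0:
        raise InvalidParameterError("mass stopping power must be > 0")
    return (mass_stopping_power_air * spec.air_density_d * spec.gap_g * 1e6
            / spec.w_value)


def particles_per_mu(gain_G: float, spec: MonitorSpec) -> float:
    """Number of particles delivered per MU for a monitor gain ``gain_G``."""
    if gain_G <= 0:
        raise InvalidParameterError("monitor gain must be > 0")
    return spec.charge_per_mu * 1e-9 / (gain_G * spec.elementary_charge)
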