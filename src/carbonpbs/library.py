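"""Beam library: everything the dose engine and optimizer need for one nozzle."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

from .biology import LqTable
from .depthdose import StoppingPowerCurve
from .engine import BeamRecord
from .lateral import ScatteringParams
from .units import MonitorSpec


@dataclass
class BeamLibrary:
    """All beam records of a facility plus the shared physics tables.

    Beams are prepared on a 3-mm range ladder: every beam's water range is a
    multiple of 3 mm, formed by combining accelerator energies with binary
    range-shifter thicknesses.
    """

    beams: Dict[str, BeamRecord]
    lq: LqTable
    monitor: MonitorSpec
    scattering: ScatteringParams
    stopping: StoppingPowerCurve
    meta: dict = field(default_factory=dict)

    def beam_for_range(self, water_range: float, tol: float = 0.5) -> BeamRecord:
        """The beam whose range matches ``water_range`` within ``tol`` mm."""
        best = None
        for b in self.beams.values():
            d = abs(b.water_range - water_range)
            if d <= tol and (best is None or d < abs(best.water_range - water_range)):
                best = b
        if best is None:
            from .errors import InvalidParameterError
            raise InvalidParameterError(
                f"no beam with range {water_range} mm in the library")
        return best

    @property
    def range_span(self) -> tuple:
        ranges = [b.water_range for b in self.beams.values()]
        return (min(ranges), max(ranges))
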