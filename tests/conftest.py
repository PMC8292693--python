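"""Shared fixtures: synthetic truth, beam libraries, modeling-chain products.

Everything is generated at test time from the synthetic truth model; the
expensive fixtures are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

import carbonpbs as c
from carbonpbs import modeling
from carbonpbs.cli import DEPTH_FRACTIONS


@pytest.fixture(scope="session")
def truth():
    return c.SyntheticTruth(seed=0)


@pytest.fixture(scope="session")
def stopping(truth):
    return c.make_stopping_power(truth)


@pytest.fixture(scope="session")
def library(truth):
    """Full default beam ladder (12 energies, shifters 0-21 mm)."""
    lib, _ = c.make_beam_library(truth)
    return lib


@pytest.fixture(scope="session")
def small_ladder(truth):
    """Three-energy ladder around 130-200 mm range, with raw measurements."""
    energies = [float(truth.energy_of_range(r)) for r in (201.0, 177.0, 153.0)]
    return c.make_beam_library(truth, energies=energies)


def frame_measurement_set(lib, beam_ids, w_per_spot=0.02,
                          fractions=DEPTH_FRACTIONS):
    patterns = {pid: modeling.generate_frame_pattern(i, o)
                for pid, (i, o) in modeling.STANDARD_PATTERNS.items()}
    out = []
    for bid in beam_ids:
        beam = lib.beams[bid]
        for f in fractions:
            depth = min(f * beam.water_range, 345.0)
            for pid, pat in patterns.items():
                dose = modeling.frame_center_dose(pat, beam, depth, w_per_spot)
                out.append(modeling.FrameMeasurement(
                    beam_id=bid, pattern_id=pid, depth=depth, dose=dose,
                    w_per_spot=w_per_spot))
    return out


@pytest.fixture(scope="session")
def modeled_chain(small_ladder):
    """Truth library, measurement set, and the chain-modeled library."""
    lib, mset = small_ladder
    frame_beams = [bid for bid, b in lib.beams.items() if b.shifter_wet == 0]
    ms = frame_measurement_set(lib, frame_beams)
    modeled = modeling.model_beam_library(mset, ms, seed=0)
    return lib, mset, modeled
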