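"""Documented text formats tying the modules together.

Conventions: all lengths in mm, doses in Gy (physical) or GyE (biological/
clinical), LET in keV/um, angles in rad.  Depth z is water-equivalent depth
from the phantom surface; lateral coordinates are at the isocenter plane
with the beam along +z.

* Beam library: a directory with ``library.yaml`` (metadata, phase spaces,
  fragment-model constants, shared physics) plus one columnar TSV per beam
  for the depth-dose set and one for the radiation-quality curves.
* Spot list: columnar text (beam id, x, y, MU) whose header MUST carry the
  plan scale factor ``f_scale`` -- a spot file without its scale factor
  cannot reproduce the clinical dose, so reading one is a hard error.
* Dose grid: a one-line JSON header (dims, spacing, origin, units) followed
  by one value per line in C order.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

from .biology import LqTable, RadiationQuality
from .depthdose import DepthDoseSet, StoppingPowerCurve
from .engine import BeamRecord, DoseGrid, Spot, SpotList
from .errors import SchemaError
from .lateral import (AxisMoments, FragmentIddModel, FragmentSigmaModel,
                      PhaseSpace, ScatteringParams)
from .library import BeamLibrary
from .units import MonitorSpec

_FLOAT_FMT = "%.17g"


class RunConfig(BaseModel):
    """Validated configuration of a dose-calculation / optimization run."""

    beam_library: str
    spot_list: Optional[str] = None
    grid_origin: tuple[float, float, float] = (-50.0, -50.0, 0.0)
    grid_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    grid_dims: tuple[int, int, int] = (51, 51, 90)
    range_mm: Optional[float] = Field(default=None, gt=0)
    sobp_width_mm: Optional[float] = Field(default=None, gt=0)
    field_mm: Optional[float] = Field(default=None, gt=0)
    prescription_gye: Optional[float] = Field(default=None, gt=0)
    seed: int = 0
    verbosity: int = 1


def load_run_config(path) -> RunConfig:
    try:
        data = yaml.safe_load(Path(path).read_text())
        return RunConfig(**data)
    except (ValidationError, TypeError, yaml.YAMLError) as exc:
        raise SchemaError(f"invalid run config {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# columnar TSV helpers

def _write_table(path, columns: dict, meta: dict) -> None:
    names = list(columns)
    arrs = [np.asarray(columns[n], dtype=float) for n in names]
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        fh.write("# columns: " + "\t".join(names) + "\n")
        for row in zip(*arrs):
            fh.write("\t".join(_FLOAT_FMT % v for v in row) + "\n")


def _read_table(path):
    meta = {}
    names = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    raise SchemaError(f"{path}:{lineno}: malformed header line")
                k, v = body.split(":", 1)
                if k.strip() == "columns":
                    names = v.split()
                else:
                    meta[k.strip()] = v.strip()
            else:
                try:
                    rows.append([float(t) for t in line.split()])
                except ValueError as exc:
                    raise SchemaError(f"{path}:{lineno}: non-numeric field") from exc
    if names is None:
        raise SchemaError(f"{path}: missing '# columns:' header")
    data = np.asarray(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] != len(names):
        raise SchemaError(f"{path}: column count mismatch with header")
    return meta, {n: data[:, i] for i, n in enumerate(names)}


# ---------------------------------------------------------------------------
# spot lists

def write_spot_list(path, spots: SpotList, beams: Optional[dict] = None) -> None:
    """Spot file: beam id, energy label, shifter, x, y, MU; f_scale in header."""
    with open(path, "w") as fh:
        fh.write(f"# f_scale: {_FLOAT_FMT % spots.f_scale}\n")
        fh.write("# columns: beam_id\tenergy\tshifter_wet\tx\ty\tw\n")
        for s in spots.spots:
            if beams and s.beam_id in beams:
                b = beams[s.beam_id]
                energy, wet = b.energy, b.shifter_wet
            else:
                energy, wet = float("nan"), float("nan")
            fh.write(f"{s.beam_id}\t{_FLOAT_FMT % energy}\t{_FLOAT_FMT % wet}"
                     f"\t{_FLOAT_FMT % s.x}\t{_FLOAT_FMT % s.y}"
                     f"\t{_FLOAT_FMT % s.w}\n")


def read_spot_list(path) -> SpotList:
    f_scale = None
    spots = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("f_scale:"):
                    f_scale = float(body.split(":", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise SchemaError(f"{path}:{lineno}: expected 6 fields, "
                                  f"got {len(parts)}")
            try:
                spots.append(Spot(float(parts[3]), float(parts[4]),
                                  parts[0], float(parts[5])))
            except ValueError as exc:
                raise SchemaError(f"{path}:{lineno}: {exc}") from exc
    if f_scale is None:
        raise SchemaError(
            f"{path}: spot file without an 'f_scale' header cannot reproduce "
            "the clinical dose; refusing to read it")
    return SpotList(spots=spots, f_scale=f_scale)


# ---------------------------------------------------------------------------
# dose grids

def write_dose_grid(path, grid: DoseGrid, units: str = "Gy") -> None:
    header = {"dims": list(grid.dims), "spacing": list(map(float, grid.spacing)),
              "origin": list(map(float, grid.origin)), "units": units}
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        for v in grid.data.ravel(order="C"):
            fh.write(_FLOAT_FMT % v + "\n")


def read_dose_grid(path) -> DoseGrid:
    with open(path) as fh:
        try:
            header = json.loads(fh.readline())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}:1: invalid JSON header") from exc
        for key in ("dims", "spacing", "origin"):
            if key not in header:
                raise SchemaError(f"{path}: header missing '{key}'")
        vals = np.array([float(line) for line in fh if line.strip()])
    dims = tuple(header["dims"])
    if vals.size != int(np.prod(dims)):
        raise SchemaError(f"{path}: {vals.size} values inconsistent with "
                          f"dims {dims}")
    return DoseGrid(origin=np.array(header["origin"], dtype=float),
                    spacing=np.array(header["spacing"], dtype=float),
                    dims=dims, data=vals.reshape(dims, order="C"))


# ---------------------------------------------------------------------------
# beam library

def _axis_to_list(a: AxisMoments):
    return [a.s11, a.s12, a.s22]


def _phase_to_dict(ps: PhaseSpace):
    return {"x": _axis_to_list(ps.x), "y": _axis_to_list(ps.y)}


def _phase_from_dict(d) -> PhaseSpace:
    return PhaseSpace(AxisMoments(*d["x"]), AxisMoments(*d["y"]))


def write_beam_library(lib: BeamLibrary, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = {
        "format": "carbonpbs-beamlib-1",
        "meta": dict(lib.meta),
        "monitor": {
            "gap_g": lib.monitor.gap_g, "w_value": lib.monitor.w_value,
            "air_density_d": lib.monitor.air_density_d,
            "charge_per_mu": lib.monitor.charge_per_mu,
            "elementary_charge": lib.monitor.elementary_charge,
        },
        "scattering": {"C": lib.scattering.C, "Z": lib.scattering.Z,
                       "A": lib.scattering.A},
        "lq_file": "lq_tables.tsv",
        "stopping_files": ["stopping_r.tsv", "stopping_e.tsv"],
        "beams": [],
    }
    _write_table(directory / "lq_tables.tsv",
                 {"let": lib.lq.let_grid, "alpha_c": lib.lq.alpha_c,
                  "beta_c": lib.lq.beta_c, "alpha_he": lib.lq.alpha_he,
                  "beta_he": lib.lq.beta_he},
                 {"alpha_x": lib.lq.alpha_x, "beta_x": lib.lq.beta_x,
                  "clinical_factor": lib.lq.clinical_factor,
                  "units": "LET keV/um; alpha Gy^-1; beta Gy^-2"})
    _write_table(directory / "stopping_r.tsv",
                 {"r": lib.stopping.r_grid, "s": lib.stopping.s_r},
                 {"units": "r mm water; S MeV/mm"})
    _write_table(directory / "stopping_e.tsv",
                 {"e": lib.stopping.e_grid, "s": lib.stopping.s_e},
                 {"units": "E MeV/n; S MeV/mm"})
    for bid, b in sorted(lib.beams.items()):
        safe = bid.replace("/", "_")
        dd_file = f"beam_{safe}_depthdose.tsv"
        q_file = f"beam_{safe}_quality.tsv"
        _write_table(directory / dd_file,
                     {"z": b.dds.z, "idd1": b.dds.idd1, "idd2": b.dds.idd2,
                      "idd3": b.dds.idd3, "idd_frag": b.dds.idd_frag},
                     {"beam_id": bid, "absolute": b.dds.absolute,
                      "units": "z mm water; IDD Gy*mm^2/MU"})
        if b.quality is not None:
            _write_table(directory / q_file,
                         {"z": b.quality.z, "let_c": b.quality.let_c,
                          "let_frag": b.quality.let_frag,
                          "alpha_c_direct": b.quality.alpha_c_direct,
                          "r": b.quality.r},
                         {"beam_id": bid,
                          "units": "z mm; LET keV/um; alpha Gy^-1"})
        index["beams"].append({
            "beam_id": bid, "energy": b.energy,
            "shifter_wet": b.shifter_wet, "water_range": b.water_range,
            "depthdose_file": dd_file,
            "quality_file": q_file if b.quality is not None else None,
            "phase_space": _phase_to_dict(b.phase_space),
            "base_phase_space": _phase_to_dict(b.base_phase_space),
            "sigma_model": {"c1": b.sigma_model.c1, "c2": b.sigma_model.c2,
                            "c3": b.sigma_model.c3, "zp": b.sigma_model.zp,
                            "sigma3": b.sigma_model.sigma3},
            "idd_model": {"c4": b.idd_model.c4, "c5": b.idd_model.c5,
                          "c6": b.idd_model.c6, "zp": b.idd_model.zp},
        })
    with open(directory / "library.yaml", "w") as fh:
        yaml.safe_dump(index, fh, sort_keys=False)


def read_beam_library(directory) -> BeamLibrary:
    directory = Path(directory)
    index_path = directory / "library.yaml"
    if not index_path.exists():
        raise SchemaError(f"{index_path}: not found")
    index = yaml.safe_load(index_path.read_text())
    if index.get("format") != "carbonpbs-beamlib-1":
        raise SchemaError(f"{index_path}: unknown format "
                          f"{index.get('format')!r}")
    lq_meta, lq_cols = _read_table(directory / index["lq_file"])
    lq = LqTable(let_grid=lq_cols["let"], alpha_c=lq_cols["alpha_c"],
                 beta_c=lq_cols["beta_c"], alpha_he=lq_cols["alpha_he"],
                 beta_he=lq_cols["beta_he"],
                 alpha_x=float(lq_meta["alpha_x"]),
                 beta_x=float(lq_meta["beta_x"]),
                 clinical_factor=float(lq_meta["clinical_factor"]))
    _, sr = _read_table(directory / index["stopping_files"][0])
    _, se = _read_table(directory / index["stopping_files"][1])
    stopping = StoppingPowerCurve(r_grid=sr["r"], s_r=sr["s"],
                                  e_grid=se["e"], s_e=se["s"])
    mon = index["monitor"]
    monitor = MonitorSpec(**mon)
    sc = index["scattering"]
    scattering = ScatteringParams(C=sc["C"], Z=sc["Z"], A=sc["A"])
    beams = {}
    for rec in index["beams"]:
        _, dd = _read_table(directory / rec["depthdose_file"])
        dds = DepthDoseSet(z=dd["z"], idd1=dd["idd1"], idd_frag=dd["idd_frag"],
                           idd2=dd["idd2"], idd3=dd["idd3"], absolute=True)
        quality = None
        if rec.get("quality_file"):
            _, q = _read_table(directory / rec["quality_file"])
            quality = RadiationQuality(z=q["z"], let_c=q["let_c"],
                                       let_frag=q["let_frag"],
                                       alpha_c_direct=q["alpha_c_direct"],
                                       r=q["r"])
        sm = rec["sigma_model"]
        im = rec["idd_model"]
        beams[rec["beam_id"]] = BeamRecord(
            beam_id=rec["beam_id"], energy=rec["energy"],
            shifter_wet=rec["shifter_wet"], water_range=rec["water_range"],
            dds=dds, phase_space=_phase_from_dict(rec["phase_space"]),
            base_phase_space=_phase_from_dict(rec["base_phase_space"]),
            scattering=scattering,
            sigma_model=FragmentSigmaModel(**sm),
            idd_model=FragmentIddModel(**im),
            quality=quality)
    return BeamLibrary(beams=beams, lq=lq, monitor=monitor,
                       scattering=scattering, stopping=stopping,
                       meta=index.get("meta", {}))
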