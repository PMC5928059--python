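"""Configuration files, result writers and the run manifest.

Configs are YAML with the same vocabulary as :class:`SimulationConfig`
(nested ``geometry`` / ``load`` / ``tissue_library`` sections); unknown keys
are rejected so typos fail loudly.  Field snapshots are written as ASCII VTK
unstructured grids (VTU) readable by ParaView and friends; the IFM series as
a plain CSV.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fem import LoadCase, StimulusConstants
from .geometry import GeometryParams
from .healing import HealingHistory, SimulationConfig, healing_day_stimulus, \
    ifm_minimum_day
from .materials import TissueLibrary
from .mesh import Mesh

__all__ = [
    "ConfigError", "load_config", "dump_config", "write_snapshot",
    "read_snapshot", "write_ifm_series", "write_summary", "write_manifest",
    "verify_manifest",
]


class ConfigError(ValueError):
    pass


_NESTED = {
    "geometry": GeometryParams,
    "load": LoadCase,
    "stimulus_constants": StimulusConstants,
}


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def load_config(path) -> SimulationConfig:
    """Read and validate a simulation configuration file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    data = dict(raw)
    for key, cls in _NESTED.items():
        if key in data and data[key] is not None:
            if not isinstance(data[key], dict):
                raise ConfigError(f"{path}: {key} must be a mapping")
            data[key] = _build(cls, data[key], f"{key} section")
    if "tissue_library" in data and data["tissue_library"] is not None:
        try:
            data["tissue_library"] = TissueLibrary.from_dict(data["tissue_library"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: invalid tissue_library: {exc}") from exc
    return _build(SimulationConfig, data, f"config {path.name}")


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.geometry is None:
        d.pop("geometry")
    d["tissue_library"] = config.tissue_library.to_dict()
    return d


def dump_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def builtin_config(case: str) -> Path:
    """Path of the packaged case_A / case_B configuration file."""
    from importlib.resources import files
    return Path(str(files("ossify") / "configs" / f"case_{case}.yaml"))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_snapshot(mesh: Mesh, fields: dict[str, np.ndarray], day: int,
                   path) -> Path:
    """ASCII VTU snapshot with one cell-data array per field."""
    if not fields:
        raise ValueError("no fields to write")
    ne = mesh.n_elements
    for name, arr in fields.items():
        if np.asarray(arr).shape != (ne,):
            raise ValueError(f"field {name!r} is not per-element")
    path = Path(path)
    conn = []
    offsets = []
    types = []
    off = 0
    for etype, cells in mesh.cell_blocks:
        for row in cells:
            conn.extend(int(i) for i in row)
            off += len(row)
            offsets.append(off)
            types.append(etype.vtk_id)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        f'<!-- day {day} -->',
        '<UnstructuredGrid>',
        f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{ne}">',
        '<Points>',
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        "\n".join(" ".join(f"{v:.10g}" for v in p) for p in mesh.nodes),
        '</DataArray>', '</Points>', '<Cells>',
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        " ".join(map(str, conn)),
        '</DataArray>',
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        " ".join(map(str, offsets)),
        '</DataArray>',
        '<DataArray type="UInt8" Name="types" format="ascii">',
        " ".join(map(str, types)),
        '</DataArray>', '</Cells>', '<CellData>',
    ]
    for name, arr in fields.items():
        lines.append(f'<DataArray type="Float64" Name="{name}" format="ascii">')
        lines.append(" ".join(f"{float(v):.17g}" for v in np.asarray(arr)))
        lines.append('</DataArray>')
    lines += ['</CellData>', '</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    path.write_text("\n".join(lines))
    return path


def read_snapshot(path) -> dict[str, np.ndarray]:
    """Cell-data arrays of a VTU file written by :func:`write_snapshot`."""
    root = ET.parse(path).getroot()
    out = {}
    for da in root.iter("DataArray"):
        name = da.get("Name")
        if name in (None, "connectivity", "offsets", "types"):
            continue
        out[name] = np.array(da.text.split(), dtype=float)
    return out


def write_ifm_series(history: HealingHistory, path) -> Path:
    """CSV: day, IFM (mm), peak callus stimulus and mean field values."""
    if not history.days:
        raise ValueError("empty history")
    path = Path(path)
    history.to_frame().to_csv(path, index=False, float_format="%.12g")
    return path


def write_summary(history: HealingHistory, config: SimulationConfig, path) -> Path:
    """JSON summary with the healing-day markers."""
    path = Path(path)
    summary = {
        "case": config.case,
        "days_simulated": len(history.days),
        "n_elements": history.n_elements,
        "day1_ifm_mm": history.ifm[0],
        "final_ifm_mm": history.ifm[-1],
        "healing_day_stimulus": healing_day_stimulus(
            history, config.physiological_s, config.sustain_days),
        "ifm_minimum_day": ifm_minimum_day(history),
        "final_mean_c_bone": history.mean_c_bone[-1],
        "final_mean_c_cart": history.mean_c_cart[-1],
        "final_mean_perfusion": history.mean_perfusion[-1],
    }
    path.write_text(json.dumps(summary, indent=2))
    return path


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(out_dir, config: SimulationConfig,
                   started: float, finished: float) -> Path:
    """Inventory of an output directory with checksums."""
    from . import __version__
    out_dir = Path(out_dir)
    files = sorted(p for p in out_dir.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "software": f"ossify {__version__}",
        "started": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(started)),
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(finished)),
        "config": config_to_dict(config),
        "files": {p.name: _sha256(p) for p in files},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def verify_manifest(out_dir) -> bool:
    """True iff every listed file exists and matches its checksum."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    for name, digest in manifest["files"].items():
        p = out_dir / name
        if not p.is_file() or _sha256(p) != digest:
            return False
    return True
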