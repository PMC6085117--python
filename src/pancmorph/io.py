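"""Readers/writers for clone tables, network JSON, configs and provenance.

Formats:

* clone tables -- comma-separated UTF-8 with header, columns exactly
  ``clone_id, mouse_id, color, x_um, y_um, z_um, vol_acinar_um3,
  vol_ductal_um3, vol_islet_um3, n_branches, induction, collection``;
* ductal networks -- JSON node-link documents mirroring the in-memory types,
  lossless round trip at full float precision;
* configs -- YAML with unknown keys rejected;
* provenance -- a JSON record (config + seed + version) written beside every
  CLI output directory so runs can be regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network import DuctalNetwork, NetworkStructureError, Segment, Terminus, validate_network
from .stats import COLORS

__all__ = [
    "CLONE_COLUMNS",
    "CloneTableError",
    "read_clone_table",
    "write_clone_table",
    "read_network",
    "write_network",
    "load_config",
    "write_provenance",
]

CLONE_COLUMNS = [
    "clone_id", "mouse_id", "color", "x_um", "y_um", "z_um",
    "vol_acinar_um3", "vol_ductal_um3", "vol_islet_um3",
    "n_branches", "induction", "collection",
]

_VOL_COLS = ["vol_acinar_um3", "vol_ductal_um3", "vol_islet_um3"]


class CloneTableError(ValueError):
    """Malformed clone table; the message names the offending row/column."""


def read_clone_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a clone table; row numbers are 1-based data rows."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"clone_id": str, "mouse_id": str,
                                  "color": str, "induction": str,
                                  "collection": str},
                     float_precision="round_trip")
    missing = [c for c in CLONE_COLUMNS if c not in df.columns]
    if missing:
        raise CloneTableError(f"{path.name}: missing column(s) {missing}")
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if row.color not in COLORS:
            raise CloneTableError(
                f"{path.name} row {i}: unknown color {row.color!r} "
                f"(column 'color')")
        vols = [row.vol_acinar_um3, row.vol_ductal_um3, row.vol_islet_um3]
        for col, v in zip(_VOL_COLS, vols):
            if not np.isfinite(v) or v < 0:
                raise CloneTableError(
                    f"{path.name} row {i}: invalid volume {v} (column {col!r})")
        if all(v == 0 for v in vols):
            raise CloneTableError(
                f"{path.name} row {i}: all compartment volumes are zero")
    return df[CLONE_COLUMNS]


def write_clone_table(clones: pd.DataFrame, path: Union[str, Path]) -> None:
    missing = [c for c in CLONE_COLUMNS if c not in clones.columns]
    if missing:
        raise CloneTableError(f"cannot write table missing columns {missing}")
    # shortest round-trip float repr so write(read(x)) is byte-identical
    clones[CLONE_COLUMNS].to_csv(path, index=False,
                                 float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# network JSON
# ---------------------------------------------------------------------------

def _poly_to_json(arr: np.ndarray) -> list:
    return [[float(x), float(y)] for x, y in np.asarray(arr)]


def write_network(network: DuctalNetwork, path: Union[str, Path]) -> None:
    doc = {
        "central_duct": _poly_to_json(network.central_duct),
        "segments": [
            {
                "id": s.id, "parent_id": s.parent_id,
                "subtree_id": s.subtree_id, "generation": s.generation,
                "polyline": _poly_to_json(s.polyline),
                **({"labels": {str(k): v for k, v in s.labels.items()}}
                   if s.labels is not None else {}),
            }
            for s in sorted(network.segments.values(), key=lambda s: s.id)
        ],
        "termini": [
            {
                "id": t.id,
                "position": [float(t.position[0]), float(t.position[1])],
                "direction": [float(t.direction[0]), float(t.direction[1])],
                "active": bool(t.active), "segment_id": t.segment_id,
            }
            for t in sorted(network.termini.values(), key=lambda t: t.id)
        ],
        "meta": {"truncated": bool(network.meta.get("truncated", False))},
    }
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_network(path: Union[str, Path]) -> DuctalNetwork:
    """Parse and structurally validate a network JSON document.

    A truncated or malformed file raises before any partial object escapes.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise NetworkStructureError(f"{path}: not valid JSON ({err})") from err
    try:
        segments = {
            s["id"]: Segment(
                id=s["id"], parent_id=s["parent_id"],
                subtree_id=s["subtree_id"], generation=s["generation"],
                polyline=np.asarray(s["polyline"], dtype=float),
                labels=({_parse_label(k): v for k, v in s["labels"].items()}
                        if "labels" in s else None),
            )
            for s in doc["segments"]
        }
        termini = {
            t["id"]: Terminus(
                id=t["id"], position=np.asarray(t["position"], float),
                direction=np.asarray(t["direction"], float),
                active=t["active"], segment_id=t["segment_id"],
            )
            for t in doc.get("termini", [])
        }
        net = DuctalNetwork(
            central_duct=np.asarray(doc["central_duct"], dtype=float),
            segments=segments, termini=termini,
            meta=dict(doc.get("meta", {})),
        )
    except (KeyError, TypeError, ValueError) as err:
        raise NetworkStructureError(f"{path}: malformed network ({err})") from err
    validate_network(net)
    return net


def _parse_label(key: str):
    # label keys serialize as strings; recover ints (0 = unlabeled) where possible
    try:
        return int(key)
    except ValueError:
        return key


# ---------------------------------------------------------------------------
# config + provenance
# ---------------------------------------------------------------------------

def load_config(path: Union[str, Path], dataclass_type):
    """Load a YAML parameter block into a dataclass, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(dataclass_type)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return dataclass_type(**raw)


def write_provenance(out_dir: Union[str, Path], command: str, seed: Optional[int],
                     config: Optional[dict] = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rec = {
        "tool": "pancmorph", "version": __version__,
        "command": command, "seed": seed,
        "config": _jsonable(config or {}),
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(rec, indent=1, sort_keys=True) + "\n")
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
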