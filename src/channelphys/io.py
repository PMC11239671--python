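"""File formats, run configuration and result envelopes.

Only text formats are used: CSV with a ``# key=value`` metadata header
for traces and tables, JSON for solutions, configurations and results,
and single-model PDB files (coordinates only) for lipid-geometry
convenience.  No acquisition-vendor binary formats are parsed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lipid_geometry import CoordinateFrame
from .synthgen import TraceRecord

__all__ = [
    "RunConfig",
    "ResultEnvelope",
    "read_trace_csv",
    "write_trace_csv",
    "read_pdb_frame",
    "read_frame_csv",
    "write_frame_csv",
]

_REQUIRED_TRACE_META = ("sampling_khz", "holding_mV")


@dataclass
class RunConfig:
    """Global run configuration; unknown keys are rejected on load."""

    seed: int = 0
    unit_system: str = "pA_mV_ms"
    output_dir: str = "."
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {"seed", "unit_system", "output_dir", "stages"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)


@dataclass
class ResultEnvelope:
    """Serializable record of one analysis stage: inputs, params, results."""

    stage: str
    version: str
    parameters: dict
    results: dict
    input_digests: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @staticmethod
    def digest(path: str | Path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def to_json(self, path: str | Path | None = None) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(f"not JSON-serializable: {type(o)}")

        text = json.dumps(self.__dict__, indent=2, default=default)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def write_trace_csv(trace: TraceRecord, path: str | Path) -> None:
    """Write a trace as ``t_ms,i_pA`` CSV with a ``#`` metadata header."""
    path = Path(path)
    meta = {"sampling_khz": trace.sampling_khz,
            "holding_mV": trace.holding_mV}
    if trace.filter_khz is not None:
        meta["filter_khz"] = trace.filter_khz
    meta.update(trace.meta)
    with path.open("w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        fh.write("t_ms,i_pA\n")
        np.savetxt(fh, np.column_stack([trace.t_ms, trace.i_pA]),
                   fmt="%.9g", delimiter=",")


def read_trace_csv(path: str | Path) -> TraceRecord:
    """Read a ``t_ms,i_pA`` CSV written by :func:`write_trace_csv`.

    The ``#`` header must carry at least ``sampling_khz`` and
    ``holding_mV``; decimal parsing is locale-independent (dot only).
    """
    path = Path(path)
    meta: dict[str, object] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" not in body:
                raise ValueError(f"malformed header line in {path}: {line!r}")
            k, v = body.split("=", 1)
            try:
                meta[k.strip()] = float(v)
            except ValueError:
                meta[k.strip()] = v.strip()
    missing = [k for k in _REQUIRED_TRACE_META if k not in meta]
    if missing:
        raise ValueError(f"{path}: missing required metadata {missing}")
    df = pd.read_csv(path, skiprows=n_header)
    if not {"t_ms", "i_pA"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns t_ms,i_pA")
    sampling = float(meta.pop("sampling_khz"))
    holding = float(meta.pop("holding_mV"))
    filt = meta.pop("filter_khz", None)
    return TraceRecord(df["t_ms"].to_numpy(), df["i_pA"].to_numpy(),
                       holding, sampling,
                       None if filt is None else float(filt), meta)


# ---------------------------------------------------------------------------
# coordinate frames
# ---------------------------------------------------------------------------

def _match_selection(expr: str, name: str, chain: str, resname: str,
                     resid: int) -> bool:
    """Tiny selection language: ``name P``, ``chain A``, ``resname POP``,
    ``resid 5`` / ``resid 5-20``, combinable with ``and``."""
    for clause in expr.split(" and "):
        parts = clause.split()
        if len(parts) != 2:
            raise ValueError(f"bad selection clause {clause!r}")
        key, val = parts
        if key == "name":
            ok = name == val
        elif key == "chain":
            ok = chain == val
        elif key == "resname":
            ok = resname == val
        elif key == "resid":
            if "-" in val[1:]:  # range; leading "-" would be a negative id
                lo, hi = val[0] + val[1:].split("-", 1)[0], val[1:].split("-", 1)[1]
                ok = int(lo) <= resid <= int(hi)
            else:
                ok = resid == int(val)
        else:
            raise ValueError(f"unknown selection key {key!r}")
        if not ok:
            return False
    return True


def read_pdb_frame(path: str | Path,
                   selections: dict[str, str] | None = None
                   ) -> CoordinateFrame:
    """Read a single-model PDB file into a coordinate frame.

    Coordinates only; masses come from the element.  ``selections`` maps
    tag names (``tmd``, ``phosphorus``, ``r2_chain``, ...) to simple
    selection expressions over atom name / chain / residue; atoms
    matching no expression carry an empty tag.  Insertion-coded residues
    are read like any other.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    ids, xyz, masses, tags = [], [], [], []
    selections = selections or {}
    serial = 0
    for chain in model:
        for res in chain:
            for atom in res:
                serial += 1
                ids.append(serial)
                xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
                masses.append(atom.element.weight if atom.element else 12.011)
                tag = ""
                for t, expr in selections.items():
                    if _match_selection(expr, atom.name, chain.name,
                                        res.name, res.seqid.num):
                        tag = t
                        break
                tags.append(tag)
    if not ids:
        raise ValueError(f"{path}: no coordinate records")
    return CoordinateFrame(np.array(ids), np.array(xyz),
                           np.array(masses), np.array(tags))


def write_frame_csv(frame: CoordinateFrame, path: str | Path) -> None:
    pd.DataFrame({
        "id": frame.atom_ids, "x": frame.xyz[:, 0], "y": frame.xyz[:, 1],
        "z": frame.xyz[:, 2], "mass": frame.masses, "tag": frame.tags,
    }).to_csv(path, index=False)


def read_frame_csv(path: str | Path) -> CoordinateFrame:
    df = pd.read_csv(path, keep_default_na=False)
    need = {"id", "x", "y", "z", "mass", "tag"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(need)}")
    return CoordinateFrame(df["id"].to_numpy(),
                           df[["x", "y", "z"]].to_numpy(dtype=float),
                           df["mass"].to_numpy(dtype=float),
                           df["tag"].to_numpy(dtype=str))
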