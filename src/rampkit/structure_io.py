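"""Structure/trajectory readers and writers plus result-table output.

Coordinates are Å throughout.  Toy bundles are Cα-only; helices TM1–TM7
are stored as PDB chains A–G so that helix membership survives a PDB
round trip.  Multi-MODEL PDB files represent trajectories; a minimal XYZ
dialect is available as a faster alternative.  Wootten class-B labels
(strings like ``6.49b``) live only in the in-memory annotation table —
the PDB format has no field for them.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser

from rampkit.ensemble_pca import ConformationEnsemble

__all__ = ["Structure", "read_structure", "write_structure",
           "write_results", "HELIX_TO_CHAIN", "CHAIN_TO_HELIX"]

HELIX_TO_CHAIN = {f"TM{i}": chr(ord("A") + i - 1) for i in range(1, 8)}
HELIX_TO_CHAIN["loop"] = "L"
CHAIN_TO_HELIX = {v: k for k, v in HELIX_TO_CHAIN.items()}


@dataclass
class Structure:
    """A single Cα conformation with its per-atom annotation table.

    ``annotations`` columns: ``residue_index`` (1-based primary sequence,
    unique), ``residue_name``, ``helix``, ``wootten``.
    """

    coords: np.ndarray
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.annotations) != len(self.coords):
            raise ValueError("annotation rows must match atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def to_ensemble(self, provenance: str = "synthetic") -> ConformationEnsemble:
        return ConformationEnsemble(self.coords[None], self.annotations,
                                    provenance)

    def atom_index(self, residue_index: int) -> int:
        rows = np.flatnonzero(
            self.annotations["residue_index"].to_numpy() == residue_index)
        if len(rows) == 0:
            raise KeyError(f"residue {residue_index} not in structure")
        return int(rows[0])


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_structure(path, fmt: str | None = None,
                   provenance: str = "synthetic") -> ConformationEnsemble:
    """Read a (multi-model) PDB or XYZ file into a Cα ensemble.

    Only Cα records are kept from PDB files; every MODEL becomes a frame
    and all models must list the same atoms in the same order.
    """
    path = Path(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if fmt == "pdb":
        return _read_pdb(path, provenance)
    if fmt == "xyz":
        return _read_xyz(path, provenance)
    raise ValueError(f"unsupported format: {fmt}")


def _read_pdb(path: Path, provenance: str) -> ConformationEnsemble:
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pdb = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Biopython raises assorted types on bad input
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    frames, tables = [], []
    for model in pdb:
        coords, rows = [], []
        for chain in model:
            for residue in chain:
                if "CA" not in residue:
                    continue
                coords.append(residue["CA"].coord)
                rows.append({
                    "residue_index": residue.id[1],
                    "residue_name": residue.get_resname(),
                    "helix": CHAIN_TO_HELIX.get(chain.id, chain.id),
                    "wootten": "",
                })
        frames.append(np.asarray(coords, dtype=float))
        tables.append(pd.DataFrame(rows))
    if not frames or len(frames[0]) == 0:
        raise ValueError(f"no Cα atoms found in {path}")
    n0 = len(frames[0])
    for i, f in enumerate(frames):
        if len(f) != n0:
            raise ValueError(
                f"model {i + 1} in {path} has {len(f)} Cα atoms, expected {n0}")
    return ConformationEnsemble(np.stack(frames), tables[0], provenance)


def _read_xyz(path: Path, provenance: str) -> ConformationEnsemble:
    frames = []
    lines = path.read_text().splitlines()
    pos = 0
    names = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{pos + 1}: expected atom count") from exc
        block = lines[pos + 2: pos + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}:{pos + 1}: truncated frame")
        coords, frame_names = [], []
        for off, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{pos + 3 + off}: malformed XYZ line")
            frame_names.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if names is None:
            names = frame_names
        elif frame_names != names:
            raise ValueError(f"{path}: inconsistent atoms between frames")
        frames.append(np.asarray(coords))
        pos += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    annotations = pd.DataFrame({
        "residue_index": np.arange(1, len(names) + 1),
        "residue_name": names,
        "helix": "",
        "wootten": "",
    })
    return ConformationEnsemble(np.stack(frames), annotations, provenance)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_ATOM_FMT = ("ATOM  {serial:>5d}  CA  {resname:<3s} {chain:1s}{resid:>4d}    "
             "{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")


def write_structure(path, obj, fmt: str | None = None) -> Path:
    """Write a Structure or ConformationEnsemble as multi-MODEL PDB or XYZ."""
    path = Path(path)
    if fmt is None:
        fmt = "xyz" if path.suffix.lower() == ".xyz" else "pdb"
    if isinstance(obj, Structure):
        frames, ann = obj.coords[None], obj.annotations
    else:
        frames, ann = obj.frames, obj.annotations
    if fmt == "pdb":
        _write_pdb(path, frames, ann)
    elif fmt == "xyz":
        _write_xyz(path, frames, ann)
    else:
        raise ValueError(f"unsupported format: {fmt}")
    return path


def _write_pdb(path: Path, frames: np.ndarray, ann: pd.DataFrame) -> None:
    multi = frames.shape[0] > 1
    with open(path, "w") as fh:
        for m, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {m:>4d}\n")
            for serial, (xyz, (_, row)) in enumerate(
                    zip(frame, ann.iterrows()), start=1):
                fh.write(_ATOM_FMT.format(
                    serial=serial,
                    resname=str(row.get("residue_name", "ALA"))[:3] or "ALA",
                    chain=HELIX_TO_CHAIN.get(row.get("helix", ""), "X"),
                    resid=int(row["residue_index"]),
                    x=xyz[0], y=xyz[1], z=xyz[2]))
            fh.write("ENDMDL\n" if multi else "TER\n")
        fh.write("END\n")


def _write_xyz(path: Path, frames: np.ndarray, ann: pd.DataFrame) -> None:
    names = [str(n) for n in ann["residue_name"]]
    with open(path, "w") as fh:
        for m, frame in enumerate(frames):
            fh.write(f"{len(frame)}\nframe {m}\n")
            for name, xyz in zip(names, frame):
                fh.write(f"{name} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(tables: dict, out_dir, float_format: str = "%.6g") -> list[Path]:
    """Write result tables deterministically under ``out_dir``.

    DataFrames become ``<name>.csv`` (fixed column order, stated float
    precision); dicts/lists become ``<name>.json``.  Returns the written
    paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        if isinstance(table, pd.DataFrame):
            p = out_dir / f"{name}.csv"
            table.to_csv(p, index=False, float_format=float_format)
        else:
            p = out_dir / f"{name}.json"
            with open(p, "w") as fh:
                json.dump(table, fh, indent=2, sort_keys=True, default=_json_default)
                fh.write("\n")
        written.append(p)
    return written


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"cannot serialise {type(obj)!r}")
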