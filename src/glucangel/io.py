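"""Readers and writers: GRO / PDB / XYZ trajectories, topology sidecar TSV,
and two-column time-series TSV.

Coordinates are stored internally in angstroms.  GRO files use nanometres
and are converted on the fly.  Multi-frame GRO files are concatenated
single-frame records (the layout GROMACS tools emit); the XYZ dialect is
extended with ``box Lx Ly Lz`` (angstroms) on the comment line, since plain
XYZ carries no cell.  PDB I/O goes through MDAnalysis (CRYST1 + MODEL
records).

The topology sidecar is a TSV with one row per atom:
``atom_index  element  name  species  unit_kind  unit_id  chain_id
ring_index  donor_flag  acceptor_flag`` with 1-based atom_index in the file
and 0-based indexing in memory.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BoxDims, Frame, Topology, TOPOLOGY_COLUMNS

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "write_topology",
    "read_series",
    "write_series",
]

_NM = 10.0  # A per nm


class ParseError(ValueError):
    """Malformed record in a coordinate file; message names the line."""


def _sniff_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.upper()
        if fmt not in {"GRO", "PDB", "XYZ"}:
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in {"gro", "pdb", "xyz"}:
        return suffix.upper()
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_trajectory(path: str | Path, format: str | None = None) -> list[Frame]:
    """Read a (possibly multi-frame) coordinate file into Frames (angstroms)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _sniff_format(path, format)
    if fmt == "GRO":
        return _read_gro(path)
    if fmt == "XYZ":
        return _read_xyz(path)
    return _read_pdb(path)


def write_trajectory(path: str | Path, frames: list[Frame], format: str | None = None) -> None:
    path = Path(path)
    fmt = _sniff_format(path, format)
    if not frames:
        raise ValueError("no frames to write")
    if fmt == "GRO":
        _write_gro(path, frames)
    elif fmt == "XYZ":
        _write_xyz(path, frames)
    else:
        _write_pdb(path, frames)


# ---------------------------------------------------------------------------
# GRO: fixed-column, nm.  "%5d%-5s%5s%5d%8.3f%8.3f%8.3f"
# ---------------------------------------------------------------------------

def _read_gro(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    lineno = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i].rstrip("\n")
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                pass
        try:
            natoms = int(lines[i + 1].strip())
        except (IndexError, ValueError):
            raise ParseError(f"{path.name}:{i + 2}: expected atom count")
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise ParseError(f"{path.name}: truncated frame starting line {i + 1}")
        pos = np.empty((natoms, 3))
        names, elements = [], []
        for j, ln in enumerate(atom_lines):
            lineno = i + 3 + j
            try:
                name = ln[10:15].strip()
                pos[j] = (float(ln[20:28]), float(ln[28:36]), float(ln[36:44]))
            except (ValueError, IndexError):
                raise ParseError(f"{path.name}:{lineno}: malformed GRO atom record")
            names.append(name)
            elements.append(_element_from_name(name))
        box_idx = i + 2 + natoms
        if box_idx >= len(lines):
            raise ParseError(f"{path.name}: missing box line after line {box_idx}")
        box_fields = lines[box_idx].split()
        if len(box_fields) < 3:
            raise ParseError(f"{path.name}:{box_idx + 1}: missing box dimensions")
        if len(box_fields) > 3 and any(float(v) != 0.0 for v in box_fields[3:]):
            raise ValueError("triclinic boxes are not supported")
        box = BoxDims(*(float(v) * _NM for v in box_fields[:3]))
        frames.append(Frame(box, pos * _NM, names, elements, time=time))
        i = box_idx + 1
    if not frames:
        raise ParseError(f"{path.name}: no frames found")
    return frames


def _write_gro(path: Path, frames: list[Frame]) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            fh.write(f"glucangel t= {fr.time:.4f}\n{fr.n_atoms:5d}\n")
            for k in range(fr.n_atoms):
                resid = (k // 100000) + 1
                x, y, z = fr.positions[k] / _NM
                fh.write(
                    f"{resid % 100000:5d}{'MOL':<5s}{fr.names[k]:>5s}"
                    f"{(k + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n"
                )
            b = fr.box.lengths / _NM
            fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# XYZ: extended comment line "box Lx Ly Lz [t= T]" in angstroms
# ---------------------------------------------------------------------------

def _read_xyz(path: Path) -> list[Frame]:
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path.name}:{i + 1}: expected atom count")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        box = _parse_xyz_box(comment, path, i + 2)
        time = 0.0
        if "t=" in comment:
            try:
                time = float(comment.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                pass
        atom_lines = lines[i + 2 : i + 2 + natoms]
        if len(atom_lines) < natoms:
            raise ParseError(f"{path.name}: truncated frame starting line {i + 1}")
        pos = np.empty((natoms, 3))
        names, elements = [], []
        for j, ln in enumerate(atom_lines):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path.name}:{i + 3 + j}: XYZ record needs symbol + 3 coordinates"
                )
            try:
                pos[j] = [float(v) for v in parts[1:4]]
            except ValueError:
                raise ParseError(f"{path.name}:{i + 3 + j}: bad coordinate value")
            names.append(parts[0])
            elements.append(_element_from_name(parts[0]))
        frames.append(Frame(box, pos, names, elements, time=time))
        i += 2 + natoms
    if not frames:
        raise ParseError(f"{path.name}: no frames found")
    return frames


def _parse_xyz_box(comment: str, path: Path, lineno: int) -> BoxDims:
    tokens = comment.split()
    if "box" not in tokens:
        raise ParseError(f"{path.name}:{lineno - 1}: comment line lacks 'box Lx Ly Lz'")
    k = tokens.index("box")
    try:
        return BoxDims(*(float(v) for v in tokens[k + 1 : k + 4]))
    except (ValueError, TypeError):
        raise ParseError(f"{path.name}:{lineno - 1}: malformed box dimensions")


def _write_xyz(path: Path, frames: list[Frame]) -> None:
    with open(path, "w") as fh:
        for fr in frames:
            b = fr.box.lengths
            fh.write(f"{fr.n_atoms}\n")
            fh.write(f"box {b[0]:.6f} {b[1]:.6f} {b[2]:.6f} t= {fr.time:.4f}\n")
            for k in range(fr.n_atoms):
                x, y, z = fr.positions[k]
                fh.write(f"{fr.names[k]:<6s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


# ---------------------------------------------------------------------------
# PDB via MDAnalysis
# ---------------------------------------------------------------------------

def _pdb_cryst1(path: Path) -> np.ndarray | None:
    """CRYST1 cell from the file header.

    Fallback for multi-model files carrying a single leading CRYST1 record,
    which the MDAnalysis reader does not propagate to the timesteps.
    """
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                try:
                    return np.array(
                        [float(line[6:15]), float(line[15:24]), float(line[24:33]),
                         float(line[33:40]), float(line[40:47]), float(line[47:54])]
                    )
                except ValueError:
                    return None
    return None


def _read_pdb(path: Path) -> list[Frame]:
    import MDAnalysis as mda

    header_dims = _pdb_cryst1(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        names = [str(n) for n in u.atoms.names]
        elements = [_element_from_name(n) for n in names]
        frames = []
        for ts in u.trajectory:
            dims = ts.dimensions
            if dims is None or not np.all(dims[:3] > 0):
                dims = header_dims
            if dims is None or not np.all(dims[:3] > 0):
                raise ParseError(f"{path.name}: PDB lacks CRYST1 box")
            if not np.allclose(dims[3:], 90.0):
                raise ValueError("triclinic boxes are not supported")
            box = BoxDims(*map(float, dims[:3]))
            frames.append(
                Frame(box, ts.positions.astype(float).copy(), names, elements,
                      time=float(getattr(ts, "time", 0.0) or 0.0))
            )
    return frames


def _write_pdb(path: Path, frames: list[Frame]) -> None:
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    fr0 = frames[0]
    n = fr0.n_atoms
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("names", list(fr0.names))
    u.add_TopologyAttr("elements", [e if len(e) <= 2 else e[:2] for e in fr0.elements])
    coords = np.stack([fr.positions for fr in frames]).astype(np.float32)
    dims = np.array(
        [[fr.box.Lx, fr.box.Ly, fr.box.Lz, 90.0, 90.0, 90.0] for fr in frames],
        dtype=np.float32,
    )
    u.load_new(coords, format=MemoryReader, dimensions=dims)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=n, multiframe=len(frames) > 1) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# sidecar topology + series TSV
# ---------------------------------------------------------------------------

def write_topology(path: str | Path, topology: Topology) -> None:
    tab = topology.table[TOPOLOGY_COLUMNS].copy()
    tab["atom_index"] = tab["atom_index"] + 1  # 1-based in file
    tab["donor_flag"] = tab["donor_flag"].astype(int)
    tab["acceptor_flag"] = tab["acceptor_flag"].astype(int)
    with open(path, "w") as fh:
        for key, val in sorted(topology.meta.items()):
            fh.write(f"#meta {key}={val}\n")
        tab.to_csv(fh, sep="\t", index=False)


def read_topology(path: str | Path) -> Topology:
    import io as _io

    meta: dict = {}
    text = Path(path).read_text().splitlines(keepends=True)
    n_meta = 0
    for line in text:
        if line.startswith("#meta "):
            key, _, val = line[len("#meta "):].strip().partition("=")
            meta[key] = _coerce(val)
            n_meta += 1
        else:
            break
    tab = pd.read_csv(_io.StringIO("".join(text[n_meta:])), sep="\t")
    missing = [c for c in TOPOLOGY_COLUMNS if c not in tab.columns]
    if missing:
        raise ParseError(f"{Path(path).name}: topology missing columns {missing}")
    tab["atom_index"] = tab["atom_index"] - 1
    tab["donor_flag"] = tab["donor_flag"].astype(bool)
    tab["acceptor_flag"] = tab["acceptor_flag"].astype(bool)
    tab = tab.reset_index(drop=True)
    return Topology(tab, oh_bonds=_infer_oh_bonds(tab), meta=meta)


def _infer_oh_bonds(tab: pd.DataFrame) -> np.ndarray:
    """Pair each hydroxyl/water hydrogen with its parent oxygen.

    Hydrogens are named H<suffix> (HO2, HO3, HO6, HO1, HO4, HW1, HW2); the
    parent oxygen shares the suffix (O2, O3, ...; water HW1/HW2 -> OW) and
    lives in the same (unit_id, chain_id, ring_index) group.
    """
    bonds = []
    grouped = tab.groupby(["unit_id", "chain_id", "ring_index"], sort=False)
    for _, grp in grouped:
        oxygens = {row["name"]: i for i, row in grp.iterrows() if row["element"] == "O"}
        for i, row in grp.iterrows():
            if row["element"] != "H":
                continue
            name = row["name"]
            if name.startswith("HW"):
                target = "OW"
            elif name.startswith("HO"):
                target = "O" + name[2:]
            else:
                target = "O" + name[1:]
            if target in oxygens:
                bonds.append((oxygens[target], i))
    return np.array(bonds, dtype=int).reshape(-1, 2)


def write_series(path: str | Path, time_ps: np.ndarray, values: np.ndarray,
                 value_name: str = "value") -> None:
    df = pd.DataFrame({"time_ps": time_ps, value_name: values})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_series(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ParseError(f"{Path(path).name}: series needs two columns")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def _coerce(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    if val in {"True", "False"}:
        return val == "True"
    return val


def _element_from_name(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return "H" if ch.upper() == "H" else ch.upper()
    return "X"
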