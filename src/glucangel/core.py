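"""Coordinate/topology data model and periodic-boundary geometry.

A :class:`Frame` stores positions of all atoms in an orthorhombic periodic
box; a :class:`Topology` is a per-atom sidecar table assigning every atom to
a structural unit (nanofiber, single cellulose chain, callose chain, or
water molecule), a chain within the unit, and a pyranose-ring index along
the chain, plus hydrogen-bond donor/acceptor role flags.

Only orthorhombic boxes are supported; triclinic input raises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BoxDims",
    "AtomRecord",
    "Frame",
    "Topology",
    "minimum_image_displacement",
    "minimum_image_distance",
    "wrap_positions",
    "unwrap_chain",
    "UNIT_KINDS",
    "SPECIES",
]

UNIT_KINDS = ("nanofiber", "cellulose_chain", "callose_chain", "water")
SPECIES = ("cellulose", "callose", "water")

TOPOLOGY_COLUMNS = [
    "atom_index",
    "element",
    "name",
    "species",
    "unit_kind",
    "unit_id",
    "chain_id",
    "ring_index",
    "donor_flag",
    "acceptor_flag",
]


@dataclass(frozen=True)
class BoxDims:
    """Orthorhombic box side lengths in angstroms."""

    Lx: float
    Ly: float
    Lz: float

    def __post_init__(self) -> None:
        if not (self.Lx > 0 and self.Ly > 0 and self.Lz > 0):
            raise ValueError(f"box sides must be positive, got {self}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz], dtype=float)

    @property
    def volume(self) -> float:
        return self.Lx * self.Ly * self.Lz


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: index, element symbol, role name, position (A)."""

    index: int
    element: str
    name: str
    position: np.ndarray


@dataclass
class Frame:
    """One configuration: a box, positions (N, 3) in angstroms, atom names."""

    box: BoxDims
    positions: np.ndarray
    names: Sequence[str]
    elements: Sequence[str]
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if len(self.names) != self.n_atoms or len(self.elements) != self.n_atoms:
            raise ValueError("names/elements length must equal atom count")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def atom(self, i: int) -> AtomRecord:
        return AtomRecord(i, self.elements[i], self.names[i], self.positions[i])

    def __iter__(self) -> Iterator[AtomRecord]:
        return (self.atom(i) for i in range(self.n_atoms))


@dataclass
class Topology:
    """Per-atom unit labels as a DataFrame plus O-H bond pairs.

    ``table`` has the sidecar TSV columns; ``oh_bonds`` is an (n, 2) integer
    array of (oxygen_index, hydrogen_index) covalent pairs used as hydrogen
    bond donor groups.  ``meta`` carries sample-level flags, e.g.
    ``periodic_chains`` for bundle samples whose chains have no termini.
    """

    table: pd.DataFrame
    oh_bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TOPOLOGY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"topology table missing columns: {missing}")
        self.oh_bonds = np.asarray(self.oh_bonds, dtype=int).reshape(-1, 2)

    @property
    def n_atoms(self) -> int:
        return len(self.table)

    def validate_against(self, frame: Frame) -> None:
        if self.n_atoms != frame.n_atoms:
            raise ValueError(
                f"topology has {self.n_atoms} atoms, frame has {frame.n_atoms}"
            )

    # -- convenience selections -------------------------------------------
    def atoms_of_unit(self, unit_id: int) -> np.ndarray:
        return self.table.index[self.table["unit_id"] == unit_id].to_numpy()

    def polysaccharide_mask(self) -> np.ndarray:
        return self.table["species"].isin(["cellulose", "callose"]).to_numpy()

    def heavy_mask(self) -> np.ndarray:
        return (self.table["element"] != "H").to_numpy()

    def unit_kinds(self) -> pd.Series:
        """unit_id -> unit_kind for every unit present."""
        return self.table.groupby("unit_id")["unit_kind"].first()

    def chains(self) -> list[tuple[int, int]]:
        """All (unit_id, chain_id) pairs of polysaccharide chains."""
        t = self.table[self.polysaccharide_mask()]
        return sorted(set(zip(t["unit_id"], t["chain_id"])))


def minimum_image_displacement(
    a: np.ndarray, b: np.ndarray, box: BoxDims
) -> np.ndarray:
    """Displacement b - a mapped to the nearest periodic image.

    Works element-wise on arrays broadcastable to (..., 3); every component
    of the result lies in (-L/2, L/2].
    """
    L = box.lengths
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    d -= L * np.ceil(d / L - 0.5)
    # ceil(x - 1/2) places both +L/2 and -L/2 on the +L/2 side: (-L/2, L/2]
    return d


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: BoxDims) -> np.ndarray:
    d = minimum_image_displacement(a, b, box)
    return np.linalg.norm(d, axis=-1)


def wrap_positions(positions: np.ndarray, box: BoxDims) -> np.ndarray:
    """Map positions into [0, L) along each axis."""
    L = box.lengths
    return np.mod(positions, L)


def unwrap_chain(
    frame: Frame, topology: Topology, unit_id: int, chain_id: int | None = None
) -> np.ndarray:
    """Return continuous (unwrapped) coordinates for one chain.

    Rings are unwrapped sequentially along the chain: each ring centroid is
    placed at the minimum-image displacement from its predecessor, and the
    ring's atoms are placed at their minimum-image offsets from the (wrapped)
    centroid.  The first atom of the first ring is unchanged.

    Raises if a ring-to-ring step reaches half the shortest box side: the
    unwrap is then ambiguous.
    """
    topology.validate_against(frame)
    t = topology.table
    sel = t["unit_id"] == unit_id
    if chain_id is not None:
        sel &= t["chain_id"] == chain_id
    idx = t.index[sel].to_numpy()
    if idx.size == 0:
        raise ValueError(f"no atoms for unit {unit_id} chain {chain_id}")
    sub = t.loc[idx]
    box = frame.box
    L_half = box.lengths.min() / 2.0
    out = frame.positions.copy()

    for cid, chain_tab in sub.groupby("chain_id"):
        rings = sorted(chain_tab["ring_index"].unique())
        prev_centroid_unwrapped = None
        prev_centroid_wrapped = None
        for r in rings:
            aidx = chain_tab.index[chain_tab["ring_index"] == r].to_numpy()
            wrapped_centroid = _pbc_centroid(frame.positions[aidx], box)
            if prev_centroid_unwrapped is None:
                centroid_unwrapped = wrapped_centroid
            else:
                step = minimum_image_displacement(
                    prev_centroid_wrapped, wrapped_centroid, box
                )
                if np.linalg.norm(step) >= L_half:
                    raise ValueError(
                        f"ambiguous unwrap: ring {r} of chain {cid} jumps "
                        f"{np.linalg.norm(step):.2f} A (>= L/2)"
                    )
                centroid_unwrapped = prev_centroid_unwrapped + step
            offs = minimum_image_displacement(
                wrapped_centroid, frame.positions[aidx], box
            )
            out[aidx] = centroid_unwrapped + offs
            prev_centroid_unwrapped = centroid_unwrapped
            prev_centroid_wrapped = wrapped_centroid

    # pin the first atom: shift so it matches its original position modulo
    # nothing (the first ring's centroid is taken as-is, so the first atom is
    # already within one minimum image of its input; shift to exact identity)
    first = idx[0]
    out[idx] += frame.positions[first] - out[first]
    return out[idx]


def _pbc_centroid(positions: np.ndarray, box: BoxDims) -> np.ndarray:
    """Centroid of a compact atom group under periodic boundaries."""
    ref = positions[0]
    offs = minimum_image_displacement(ref, positions, box)
    return ref + offs.mean(axis=0)
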