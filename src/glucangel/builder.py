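"""Construction of cellulose/callose model samples.

Chains are built from a per-residue pyranose template (ring carbons C1-C6,
ring oxygen O5, hydroxyl oxygens O2/O3/O6 with hydrogens, glycosidic O4)
with a 5.2 A axial repeat for extended cellulose; callose is built as a
helix with configurable rise and residues per turn.  Nanofibers pack 10,
18 or 61 chains in the cross-sections used for native cellulose I-beta
models; hydrogels distribute fibers and single chains along the three box
axes with random axial shifts and small random tilts, following the
protocol used to assemble 10 wt % polysaccharide / 90 wt % water samples.

The geometry is intentionally schematic: downstream analyses need atom
roles, ring indices and distances, not force-field-grade coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import CELLULOSE_RING_REPEAT_A, M_GLUCOSE_RESIDUE, M_WATER
from .core import BoxDims, Frame, Topology, TOPOLOGY_COLUMNS, wrap_positions

__all__ = [
    "CompositionSpec",
    "BuiltSample",
    "build_chain",
    "build_nanofiber",
    "build_hydrogel",
    "build_bundle",
    "crystallinity_degree",
    "ideal_chain_length",
    "standard_composition",
    "STANDARD_WATER_COUNTS",
]

#: Water molecule counts recorded for the standard hydrogel compositions
#: (bookkeeping only -- water coordinates are never generated here).
STANDARD_WATER_COUNTS = {
    "100:0": 488821,
    "92:8": 487491,
    "84:16": 480305,
    "76:24": 473322,
}

_NANOFIBER_ROWS = {
    10: (2, 3, 3, 2),
    18: (2, 3, 4, 4, 3, 2),
    61: (6, 5, 6, 5, 6, 5, 6, 5, 6, 5, 6),
}

# cross-section packing, angstroms: chain spacing within a row / row stacking
DEFAULT_ROW_SPACING = 8.2
DEFAULT_SHEET_SPACING = 3.9


# ---------------------------------------------------------------------------
# residue template
# ---------------------------------------------------------------------------

_RING_R = 1.45  # hexagon circumradius of the pyranose ring, A

def _ring_template() -> tuple[list[str], np.ndarray]:
    """Atom names and local coordinates of one residue (axis = +z).

    The six ring atoms (5 C + O5) sit on a hexagon in the x-z plane so the
    ring centroid is exactly the local origin; hydroxyls point radially with
    small out-of-plane offsets; the glycosidic O4 sits half a repeat up the
    axis.
    """
    names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    angles = np.deg2rad([90.0, 30.0, -30.0, -90.0, -150.0, 150.0])
    coords = [np.array([_RING_R * np.cos(a), 0.0, _RING_R * np.sin(a)]) for a in angles]

    def radial(base: np.ndarray, out: float, y: float) -> np.ndarray:
        r = np.array([base[0], 0.0, base[2]])
        n = np.linalg.norm(r)
        return base + (r / n) * out + np.array([0.0, y, 0.0])

    c2, c3, c5 = coords[1], coords[2], coords[4]
    o2 = radial(c2, 1.40, 0.35)
    o3 = radial(c3, 1.40, -0.35)
    c6 = c5 + np.array([0.55, 1.25, -0.3])
    o6 = c6 + np.array([0.9, 1.05, 0.0])
    extra = {
        "O2": o2,
        "HO2": radial(o2, 0.96, 0.0),
        "O3": o3,
        "HO3": radial(o3, 0.96, 0.0),
        "C6": c6,
        "O6": o6,
        "HO6": o6 + np.array([0.0, 0.96, 0.0]),
        "O4": np.array([0.0, 0.0, CELLULOSE_RING_REPEAT_A / 2.0]),
    }
    names += list(extra)
    coords += list(extra.values())
    return names, np.array(coords)


_TEMPLATE_NAMES, _TEMPLATE_XYZ = _ring_template()
ATOMS_PER_RING = len(_TEMPLATE_NAMES)

_DONOR_H = {"HO1", "HO2", "HO3", "HO4", "HO6", "HW1", "HW2"}


def _rot_z(phi: float) -> np.ndarray:
    c, s = math.cos(phi), math.sin(phi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def ideal_chain_length(n_rings: int, repeat: float = CELLULOSE_RING_REPEAT_A) -> float:
    """Ideal extended chain length in angstroms: n_rings * axial repeat."""
    return n_rings * repeat


@dataclass
class ChainAtoms:
    """Atoms of one chain in local coordinates (chain axis = +z)."""

    positions: np.ndarray
    names: list[str]
    elements: list[str]
    ring_index: np.ndarray
    species: str
    oh_bonds: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=int)
    )

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


def build_chain(
    species: Literal["cellulose", "callose"],
    n_rings: int,
    conformation: Literal["extended", "helical"] = "extended",
    *,
    rise: float = 3.0,
    residues_per_turn: float = 6.0,
    helix_radius: float = 4.0,
    terminated: bool = True,
) -> ChainAtoms:
    """Build one polysaccharide chain along the +z axis.

    Extended chains place successive ring centroids ``5.2 A`` apart on the
    axis with the cellulose two-fold screw (alternate rings flipped 180
    degrees); helical chains place centroids on a helix of the given rise,
    radius and residues per turn.  Terminated chains gain complementary
    -OH/-H capping atoms (O1/HO1 on the first ring, HO4 on the last);
    ``terminated=False`` models periodically continued chains.
    """
    if species not in ("cellulose", "callose"):
        raise ValueError(f"unknown species {species!r}")
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    if conformation not in ("extended", "helical"):
        raise ValueError(f"unknown conformation {conformation!r}")

    pos_blocks, names, rings = [], [], []
    for k in range(n_rings):
        xyz = _TEMPLATE_XYZ.copy()
        if conformation == "extended":
            xyz = xyz @ _rot_z(math.pi * (k % 2)).T
            centroid = np.array([0.0, 0.0, k * CELLULOSE_RING_REPEAT_A])
        else:
            phi = 2.0 * math.pi * k / residues_per_turn
            xyz = xyz @ _rot_z(phi).T
            centroid = np.array(
                [helix_radius * math.cos(phi), helix_radius * math.sin(phi), k * rise]
            )
        pos_blocks.append(xyz + centroid)
        names.extend(_TEMPLATE_NAMES)
        rings.extend([k] * ATOMS_PER_RING)

    positions = np.concatenate(pos_blocks)
    # covalent hydroxyl O-H pairs, by template index per ring
    i_o2, i_ho2 = _TEMPLATE_NAMES.index("O2"), _TEMPLATE_NAMES.index("HO2")
    i_o3, i_ho3 = _TEMPLATE_NAMES.index("O3"), _TEMPLATE_NAMES.index("HO3")
    i_o6, i_ho6 = _TEMPLATE_NAMES.index("O6"), _TEMPLATE_NAMES.index("HO6")
    bonds = []
    for k in range(n_rings):
        base = k * ATOMS_PER_RING
        bonds += [(base + i_o2, base + i_ho2), (base + i_o3, base + i_ho3),
                  (base + i_o6, base + i_ho6)]
    if terminated:
        first_centroid = pos_blocks[0][:6].mean(axis=0)
        o1 = first_centroid + np.array([0.0, 0.0, -CELLULOSE_RING_REPEAT_A / 2.0])
        ho1 = o1 + np.array([0.0, 0.0, -0.96])
        i_last_o4 = len(positions) - ATOMS_PER_RING + _TEMPLATE_NAMES.index("O4")
        ho4 = positions[i_last_o4] + np.array([0.0, 0.0, 0.96])
        n = len(positions)
        positions = np.concatenate([positions, [o1, ho1, ho4]])
        names += ["O1", "HO1", "HO4"]
        rings += [0, 0, n_rings - 1]
        bonds += [(n, n + 1), (i_last_o4, n + 2)]

    elements = ["H" if n.startswith("H") else n[0] for n in names]
    return ChainAtoms(
        positions, names, elements, np.array(rings, dtype=int), species,
        oh_bonds=np.array(bonds, dtype=int).reshape(-1, 2),
    )


def build_nanofiber(
    n_chains: int,
    rings_per_chain: int,
    *,
    row_spacing: float = DEFAULT_ROW_SPACING,
    sheet_spacing: float = DEFAULT_SHEET_SPACING,
    terminated: bool = True,
) -> list[ChainAtoms]:
    """Build a crystalline nanofiber as a list of parallel extended chains.

    Cross-sections: 18 chains in the (2,3,4,4,3,2) row pattern, 10 chains as
    its (2,3,3,2) core, 61 chains as an 11-row rectangular block.  Chains
    run along +z; the cross-section lies in the x-y plane.
    """
    if n_chains not in _NANOFIBER_ROWS:
        raise ValueError(
            f"unsupported chain count {n_chains}; choose from {sorted(_NANOFIBER_ROWS)}"
        )
    rows = _NANOFIBER_ROWS[n_chains]
    chains = []
    y0 = -(len(rows) - 1) / 2.0 * sheet_spacing
    for i, m in enumerate(rows):
        y = y0 + i * sheet_spacing
        x0 = -(m - 1) / 2.0 * row_spacing
        for j in range(m):
            ch = build_chain("cellulose", rings_per_chain, "extended",
                             terminated=terminated)
            ch.positions = ch.positions + np.array([x0 + j * row_spacing, y, 0.0])
            chains.append(ch)
    return chains


# ---------------------------------------------------------------------------
# sample assembly
# ---------------------------------------------------------------------------

@dataclass
class CompositionSpec:
    """Per-axis-direction composition of a hydrogel sample.

    Triples are ordered (x, y, z).  The standard samples use 4 nanofibers
    and 32 single cellulose chains per direction (100:0); each callose
    substitution step replaces one 10-chain nanofiber and 8 single cellulose
    chains of one direction by 18 callose chains.
    """

    n_nanofibers: tuple[int, int, int] = (4, 4, 4)
    chains_per_fiber: int = 10
    n_single_cellulose: tuple[int, int, int] = (32, 32, 32)
    n_callose: tuple[int, int, int] = (0, 0, 0)
    rings_per_chain: int = 47
    callose_rings_per_chain: int = 48
    box_side: float = 250.0
    min_clearance: float = 10.0
    max_tilt_deg: float = 5.0
    seed: int = 0
    name: str = "custom"
    water_molecules: int = 0

    def __post_init__(self) -> None:
        for tup in (self.n_nanofibers, self.n_single_cellulose, self.n_callose):
            if any(n < 0 for n in tup):
                raise ValueError("unit counts must be >= 0")
        if self.box_side < ideal_chain_length(self.rings_per_chain):
            raise ValueError(
                "box_side smaller than the ideal extended chain length"
            )


def standard_composition(name: str, seed: int = 0,
                         replace_order: str = "xyz") -> CompositionSpec:
    """CompositionSpec for one of the standard samples 100:0 ... 76:24.

    ``replace_order`` states which axis direction loses its nanofiber first
    at each callose substitution step.
    """
    steps = {"100:0": 0, "92:8": 1, "84:16": 2, "76:24": 3}
    if name not in steps:
        raise ValueError(f"unknown standard composition {name!r}")
    order = ["xyz".index(c) for c in replace_order]
    fibers, singles, callose = [4, 4, 4], [32, 32, 32], [0, 0, 0]
    for step in range(steps[name]):
        d = order[step % 3]
        fibers[d] -= 1
        singles[d] -= 8
        callose[d] += 18
    return CompositionSpec(
        n_nanofibers=tuple(fibers),
        n_single_cellulose=tuple(singles),
        n_callose=tuple(callose),
        seed=seed,
        name=name,
        water_molecules=STANDARD_WATER_COUNTS[name],
    )


@dataclass
class BuiltSample:
    """A constructed configuration with its topology and composition report."""

    frame: Frame
    topology: Topology
    report: dict = field(default_factory=dict)


class PlacementError(RuntimeError):
    """Raised when clearance cannot be satisfied within the retry budget."""


_AXIS_ROTATIONS = {
    0: np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]]),  # z->x
    1: np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0], [0.0, -1.0, 0.0]]),  # z->y
    2: np.eye(3),
}


def _small_tilt(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    ax, ay = np.deg2rad(rng.uniform(-max_deg, max_deg, size=2))
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    return rx @ ry


class _SampleAccumulator:
    """Collects placed units into frame + topology arrays."""

    def __init__(self, box: BoxDims):
        self.box = box
        self.rows: list[dict] = []
        self.positions: list[np.ndarray] = []
        self.oh_bonds: list[tuple[int, int]] = []
        self.n_atoms = 0
        self.next_unit = 0

    def add_unit(
        self,
        chains: Sequence[ChainAtoms],
        unit_kind: str,
        coords_per_chain: Sequence[np.ndarray],
    ) -> int:
        uid = self.next_unit
        self.next_unit += 1
        for cid, (ch, xyz) in enumerate(zip(chains, coords_per_chain)):
            start = self.n_atoms
            wrapped = wrap_positions(xyz, self.box)
            self.positions.append(wrapped)
            species = ch.species
            for a in range(ch.n_atoms):
                name = ch.names[a]
                self.rows.append(
                    {
                        "atom_index": start + a,
                        "element": ch.elements[a],
                        "name": name,
                        "species": species,
                        "unit_kind": unit_kind,
                        "unit_id": uid,
                        "chain_id": cid,
                        "ring_index": int(ch.ring_index[a]),
                        "donor_flag": name in _DONOR_H
                        or name in {"O1", "O2", "O3", "O6"},
                        "acceptor_flag": ch.elements[a] == "O",
                    }
                )
            for o_idx, h_idx in ch.oh_bonds:
                self.oh_bonds.append((start + int(o_idx), start + int(h_idx)))
            self.n_atoms += ch.n_atoms
        return uid

    def finish(self, meta: dict | None = None) -> tuple[Frame, Topology]:
        if self.positions:
            pos = np.concatenate(self.positions)
        else:
            pos = np.empty((0, 3))
        tab = pd.DataFrame(self.rows, columns=TOPOLOGY_COLUMNS)
        if tab.empty:
            tab = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
                TOPOLOGY_COLUMNS,
                [int, str, str, str, str, int, int, int, bool, bool])})
        frame = Frame(
            self.box, pos, list(tab["name"]), list(tab["element"])
        )
        topo = Topology(tab, oh_bonds=np.array(self.oh_bonds, dtype=int).reshape(-1, 2),
                        meta=meta or {})
        return frame, topo


def _place_direction_units(
    acc: _SampleAccumulator,
    units: list[tuple[str, list[ChainAtoms]]],
    direction: int,
    box: BoxDims,
    min_clearance: float,
    max_tilt_deg: float,
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> None:
    """Place units aligned along one axis with same-direction clearance.

    Clearance is checked between atoms of units sharing this axis direction
    (minimum image); see the methods note for why crossing-direction pairs
    are exempt.
    """
    R_axis = _AXIS_ROTATIONS[direction]
    L = box.lengths
    placed_atoms: np.ndarray | None = None
    tree: cKDTree | None = None
    placed_count = 0
    for kind, chains in units:
        local = np.concatenate([c.positions for c in chains])
        sizes = [c.n_atoms for c in chains]
        ok = False
        for _ in range(max_retries):
            rot = R_axis @ _small_tilt(rng, max_tilt_deg)
            offset = rng.uniform(0.0, L)
            xyz = wrap_positions(local @ rot.T + offset, box)
            if tree is None:
                ok = True
            else:
                d, _idx = tree.query(xyz, k=1, distance_upper_bound=min_clearance)
                ok = np.all(np.isinf(d))
            if ok:
                splits = np.cumsum(sizes)[:-1]
                acc.add_unit(chains, kind, np.split(local @ rot.T + offset, splits))
                placed_atoms = (
                    xyz if placed_atoms is None else np.vstack([placed_atoms, xyz])
                )
                tree = cKDTree(placed_atoms, boxsize=L)
                placed_count += 1
                break
        if not ok:
            raise PlacementError(
                f"could not place unit {placed_count + 1}/{len(units)} along axis "
                f"{'xyz'[direction]} at clearance {min_clearance} A after "
                f"{max_retries} retries ({placed_count} units placed)"
            )


def build_hydrogel(spec: CompositionSpec) -> BuiltSample:
    """Assemble a hydrogel configuration from a CompositionSpec.

    Nanofibers and single chains are grouped by axis direction, each given
    a small random tilt, a random cross-sectional position subject to
    same-direction clearance, and a uniform random axial shift.  Water is
    recorded in the composition report but never given coordinates.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    box = BoxDims(spec.box_side, spec.box_side, spec.box_side)
    acc = _SampleAccumulator(box)

    for d in range(3):
        units: list[tuple[str, list[ChainAtoms]]] = []
        for _ in range(spec.n_nanofibers[d]):
            units.append(
                ("nanofiber", build_nanofiber(spec.chains_per_fiber, spec.rings_per_chain))
            )
        for _ in range(spec.n_single_cellulose[d]):
            units.append(
                ("cellulose_chain", [build_chain("cellulose", spec.rings_per_chain)])
            )
        for _ in range(spec.n_callose[d]):
            units.append(
                ("callose_chain",
                 [build_chain("callose", spec.callose_rings_per_chain, "helical")])
            )
        _place_direction_units(
            acc, units, d, box, spec.min_clearance, spec.max_tilt_deg, rng
        )

    frame, topo = acc.finish(meta={"sample": spec.name, "seed": spec.seed})
    report = _composition_report(spec, topo)
    return BuiltSample(frame, topo, report)


def _composition_report(spec: CompositionSpec, topo: Topology) -> dict:
    kinds = topo.unit_kinds()
    n_fibers = int((kinds == "nanofiber").sum())
    n_fiber_chains = n_fibers * spec.chains_per_fiber
    n_single_cell = int((kinds == "cellulose_chain").sum())
    n_callose = int((kinds == "callose_chain").sum())
    n_cellulose = n_fiber_chains + n_single_cell
    n_residues = (
        n_cellulose * spec.rings_per_chain + n_callose * spec.callose_rings_per_chain
    )
    mass_poly = n_residues * M_GLUCOSE_RESIDUE
    mass_water = spec.water_molecules * M_WATER
    wt = 100.0 * mass_poly / (mass_poly + mass_water) if mass_poly + mass_water else 0.0
    return {
        "sample": spec.name,
        "n_nanofibers": n_fibers,
        "n_cellulose_chains": n_cellulose,
        "n_fiber_chains": n_fiber_chains,
        "n_single_cellulose_chains": n_single_cell,
        "n_callose_chains": n_callose,
        "water_molecules": spec.water_molecules,
        "polysaccharide_wt_pct": wt,
        "seed": spec.seed,
    }


def crystallinity_degree(built: BuiltSample, ndigits: int = 0) -> float:
    """Crystallinity of the cellulose fraction, percent.

    Defined as the fraction of cellulose chains grouped in nanofibers:
    100 * (chains in nanofibers) / (all cellulose chains).
    """
    rep = built.report
    total = rep.get("n_cellulose_chains", 0)
    if total == 0:
        raise ValueError("crystallinity undefined: no cellulose chains")
    pct = 100.0 * rep["n_fiber_chains"] / total
    return round(pct, ndigits) if ndigits is not None else pct


def build_bundle(
    n_fibers: int = 7,
    chains_per_fiber: int = 18,
    n_callose: int = 20,
    *,
    rings_per_chain: int = 16,
    callose_rings: int = 24,
    perp_side: float = 180.0,
    fiber_ring_radius: float = 42.0,
    seed: int = 0,
) -> BuiltSample:
    """Build a dense nanofiber bundle: hexagonally arranged 18-chain fibers
    with callose chains inserted in the interstitial gaps.

    Chains are periodic along the fiber axis (no termini), so the axial box
    length equals rings_per_chain * 5.2 A; end-to-end analysis on bundle
    samples is undefined and refused downstream.
    """
    if n_fibers < 0 or n_callose < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    Lz = ideal_chain_length(rings_per_chain)
    box = BoxDims(perp_side, perp_side, Lz)
    acc = _SampleAccumulator(box)
    centre = np.array([perp_side / 2.0, perp_side / 2.0, 0.0])

    # hexagonal-like fiber centres: one in the middle, rest on a ring
    centres = [np.zeros(3)]
    for k in range(max(n_fibers - 1, 0)):
        phi = 2.0 * math.pi * k / max(n_fibers - 1, 1)
        centres.append(
            np.array([fiber_ring_radius * math.cos(phi),
                      fiber_ring_radius * math.sin(phi), 0.0])
        )
    centres = centres[:n_fibers]

    fiber_atoms = []
    for c in centres:
        chains = build_nanofiber(chains_per_fiber, rings_per_chain, terminated=False)
        shift = centre + c + np.array([0.0, 0.0, rng.uniform(0.0, Lz)])
        coords = [ch.positions + shift for ch in chains]
        acc.add_unit(chains, "nanofiber", coords)
        fiber_atoms.append(wrap_positions(np.concatenate(coords), box))

    tree = cKDTree(np.concatenate(fiber_atoms), boxsize=box.lengths) if fiber_atoms else None
    placed = 0
    for _ in range(n_callose):
        ch = build_chain("callose", callose_rings, "helical", terminated=False)
        ok = False
        for _ in range(1000):
            # interstitial region: inside the fiber ring, plus a margin
            r = (fiber_ring_radius + 15.0) * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            xy = centre[:2] + r * np.array([math.cos(phi), math.sin(phi)])
            shift = np.array([xy[0], xy[1], rng.uniform(0.0, Lz)])
            xyz = wrap_positions(ch.positions + shift, box)
            if tree is None:
                ok = True
            else:
                d, _i = tree.query(xyz, k=1, distance_upper_bound=3.0)
                ok = np.all(np.isinf(d))
            if ok:
                acc.add_unit([ch], "callose_chain", [ch.positions + shift])
                placed += 1
                break
        if not ok:
            raise PlacementError(
                f"could not place callose chain {placed + 1}/{n_callose}"
            )

    frame, topo = acc.finish(meta={"sample": "bundle", "periodic_chains": True,
                                   "seed": seed})
    report = {
        "sample": "bundle",
        "n_nanofibers": n_fibers,
        "n_cellulose_chains": n_fibers * chains_per_fiber,
        "n_fiber_chains": n_fibers * chains_per_fiber,
        "n_single_cellulose_chains": 0,
        "n_callose_chains": n_callose,
        "water_molecules": 0,
        "seed": seed,
    }
    return BuiltSample(frame, topo, report)
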