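"""Planted-truth generators for every analysis stage.

Each generator is seed-deterministic and returns its data together with a
:class:`GeneratorReport` holding the planted parameters and the ground
truth the corresponding analysis should recover.  The generators emulate
the *statistics* the analyses consume -- Gaussian box fluctuations of a
cubic elastic medium at 300 K, random-walk water, diffractograms with a
planted crystalline/total area ratio, hydrogel-like boxes of fibers and
chains -- not real molecular dynamics.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import builder
from .builder import BuiltSample, CompositionSpec, build_chain, standard_composition
from .constants import A3_PER_M3, KB_J_PER_K, PA_PER_GPA
from .core import BoxDims, Frame, Topology, TOPOLOGY_COLUMNS, wrap_positions
from .elasticity import StrainSeries, VolumeSeries, young_from_constants
from .xrd import Diffractogram, PeakTemplate, cellulose_template, _gaussian

__all__ = [
    "GeneratorReport",
    "gen_toy_hydrogel",
    "gen_crossing_fixture",
    "gen_fluctuations",
    "gen_stress_strain",
    "gen_random_walk",
    "gen_point_configs",
    "gen_diffractogram",
    "gen_hb_fixture",
    "gen_fjc_chains",
]


@dataclass
class GeneratorReport:
    generator: str
    seed: int
    planted: dict = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


# ---------------------------------------------------------------------------
# hydrogel-like boxes
# ---------------------------------------------------------------------------

def gen_toy_hydrogel(
    scale: float = 0.25,
    seed: int = 0,
    composition: str = "100:0",
    n_frames: int = 3,
    jitter: float = 0.3,
    drift: float = 0.5,
) -> tuple[BuiltSample, list[Frame], GeneratorReport]:
    """Hydrogel box at reduced counts plus a short pseudo-dynamics trajectory.

    ``scale`` multiplies the per-direction unit counts of the standard
    composition (scale 1 is the full 12-fiber/96-chain protocol; the
    minimum is 1/12 -- at least one fiber).  Pseudo-dynamics adds per-atom
    thermal jitter (sigma ``jitter`` A per frame) plus a slow rigid drift
    per chain (sigma ``drift`` A); it makes no claim of emulating MD.
    """
    if scale < 1.0 / 12.0:
        raise ValueError("scale must be >= 1/12 (at least one nanofiber)")
    base = standard_composition(composition, seed=seed)

    def scaled(tup: tuple[int, int, int]) -> tuple[int, int, int]:
        # scale the total, distribute by largest remainder so small scales
        # keep at least the units the total warrants (e.g. 1/12 -> 1 fiber)
        target = int(round(sum(tup) * scale))
        exact = [n * scale for n in tup]
        out = [int(np.floor(e)) for e in exact]
        order = np.argsort([e - f for e, f in zip(exact, out)])[::-1]
        for i in range(target - sum(out)):
            out[order[i % 3]] += 1
        return tuple(out)

    spec = dataclasses.replace(
        base,
        n_nanofibers=scaled(base.n_nanofibers),
        n_single_cellulose=scaled(base.n_single_cellulose),
        n_callose=scaled(base.n_callose),
        name=f"{composition}@{scale:g}",
    )
    built = builder.build_hydrogel(spec)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    frames = [built.frame]
    tab = built.topology.table
    unit_chain = tab.groupby(["unit_id", "chain_id"], sort=False).ngroup().to_numpy()
    n_chains_total = unit_chain.max() + 1 if len(tab) else 0
    pos = built.frame.positions.copy()
    for t in range(1, n_frames):
        drifts = rng.normal(0.0, drift, size=(n_chains_total, 3))
        pos = pos + drifts[unit_chain] + rng.normal(0.0, jitter, size=pos.shape)
        frames.append(
            Frame(built.frame.box, wrap_positions(pos, built.frame.box),
                  built.frame.names, built.frame.elements, time=float(t))
        )

    report = GeneratorReport(
        "toy_hydrogel", seed,
        planted={"scale": scale, "composition": composition,
                 "jitter_A": jitter, "drift_A": drift, "n_frames": n_frames},
        truth={
            "composition": built.report,
            "crystallinity_pct": builder.crystallinity_degree(built, ndigits=1),
        },
    )
    return built, frames, report


def gen_crossing_fixture(
    n_chains: int = 5,
    n_fibers: int = 1,
    target_distance: float = 3.0,
    chain_rings: int = 12,
    seed: int = 0,
) -> tuple[Frame, Topology, GeneratorReport]:
    """Chains planted to cross nanofibers at a known contact distance.

    ``n_fibers`` parallel 10-chain fibers run along z, far enough apart to
    never touch each other; each of the ``n_chains`` single cellulose
    chains runs along x at its own height, skimming the top of every fiber
    at ``target_distance`` angstroms (tuned numerically).  Ground truth:
    each chain forms exactly one link per fiber, fibers form no direct
    links, and no unit is isolated (for n_chains, n_fibers >= 1).
    """
    from scipy.spatial import cKDTree

    from .builder import _AXIS_ROTATIONS, _SampleAccumulator, build_nanofiber

    if n_chains < 1 or n_fibers < 1:
        raise ValueError("need at least one chain and one fiber")
    rng = np.random.default_rng(seed)
    # the chain must span every fiber cross-section
    chain_rings = max(
        chain_rings, int(np.ceil(((n_fibers - 1) * 40.0 + 50.0) / 5.2))
    )
    z_spacing = 12.0
    z_start = 14.0
    fiber_rings = int(np.ceil((z_start + n_chains * z_spacing + 10.0) / 5.2))
    Lz = fiber_rings * 5.2 + 12.0
    fiber_dx = 40.0
    Lx = max(120.0, n_fibers * fiber_dx + 80.0)
    box = BoxDims(Lx, 120.0, Lz)
    acc = _SampleAccumulator(box)

    fiber_atoms = []
    for f in range(n_fibers):
        chains = build_nanofiber(10, fiber_rings)
        centre = np.array([60.0 + f * fiber_dx, 60.0, 6.0])
        coords = [ch.positions + centre for ch in chains]
        acc.add_unit(chains, "nanofiber", coords)
        # contact criteria apply to heavy atoms: tune on those
        heavy = np.concatenate(
            [xyz[np.array(ch.elements) != "H"]
             for ch, xyz in zip(chains, coords)]
        )
        fiber_atoms.append(heavy)
    trees = [cKDTree(f) for f in fiber_atoms]
    y_top = max(f[:, 1].max() for f in fiber_atoms)

    rot = _AXIS_ROTATIONS[0]  # chain axis z -> x
    x_mid = 60.0 + (n_fibers - 1) * fiber_dx / 2.0
    for i in range(n_chains):
        ch = build_chain("cellulose", chain_rings)
        heavy_mask = np.array(ch.elements) != "H"
        local_all = ch.positions @ rot.T
        local = local_all[heavy_mask]
        x0 = x_mid - chain_rings * 5.2 / 2.0
        z_i = z_start + i * z_spacing + rng.uniform(-1.0, 1.0)

        def min_dist(yoff: float) -> float:
            # worst fiber: every fiber must come within the contact cutoff
            pts = local + np.array([x0, y_top + yoff, z_i])
            return max(float(t.query(pts, k=1)[0].min()) for t in trees)

        lo, hi = -10.0, 20.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if min_dist(mid) < target_distance:
                lo = mid
            else:
                hi = mid
        yoff = hi  # first offset at/above the target distance
        acc.add_unit([ch], "cellulose_chain",
                     [local_all + np.array([x0, y_top + yoff, z_i])])

    frame, topo = acc.finish(meta={"sample": "crossing_fixture", "seed": seed})
    report = GeneratorReport(
        "crossing_fixture", seed,
        planted={"n_chains": n_chains, "n_fibers": n_fibers,
                 "target_distance_A": target_distance},
        truth={"n_links": n_chains * n_fibers, "fiber_fiber_links": 0,
               "isolated_units": 0},
    )
    return frame, topo, report


# ---------------------------------------------------------------------------
# fluctuation series for the elastic estimators
# ---------------------------------------------------------------------------

def gen_fluctuations(
    kind: str,
    *,
    B: float | None = None,
    C11: float | None = None,
    C12: float | None = None,
    V0: float = 250.0**3,
    T: float = 300.0,
    n: int = 100_000,
    seed: int = 0,
) -> tuple[VolumeSeries | StrainSeries, GeneratorReport]:
    """Gaussian equilibrium fluctuations of a cubic elastic medium.

    ``kind='volume'``: volumes with mean V0 (A^3) and variance k_B T V0/B
    for a planted bulk modulus B (GPa).  ``kind='strain'``: zero-mean
    (eps_xx, eps_yy, eps_zz) triples with covariance k_B T S / V0 built
    from planted C11, C12 (GPa, C11 > C12).  The report stores the values
    the estimators should recover (B, or C11/C12/B/Y).
    """
    rng = np.random.default_rng(seed)
    time = np.arange(n, dtype=float)
    kbt = KB_J_PER_K * T
    v0_m3 = V0 / A3_PER_M3
    if kind == "volume":
        if B is None or B <= 0:
            raise ValueError("volume fluctuations need a planted B > 0 (GPa)")
        var_m6 = kbt * v0_m3 / (B * PA_PER_GPA)
        sigma_a3 = np.sqrt(var_m6) * A3_PER_M3
        series = VolumeSeries(time, rng.normal(V0, sigma_a3, size=n), T)
        report = GeneratorReport(
            "fluctuations_volume", seed,
            planted={"B_GPa": B, "V0_A3": V0, "T_K": T, "n": n},
            truth={"B_GPa": B},
        )
        return series, report
    if kind == "strain":
        if C11 is None or C12 is None:
            raise ValueError("strain fluctuations need planted C11, C12 (GPa)")
        if not C11 > C12:
            raise ValueError("need C11 > C12 for a stable cubic medium")
        c11, c12 = C11 * PA_PER_GPA, C12 * PA_PER_GPA
        denom = (c11 - c12) * (c11 + 2.0 * c12)
        s11 = (c11 + c12) / denom
        s12 = -c12 / denom
        cov = (kbt / v0_m3) * np.array(
            [[s11, s12, s12], [s12, s11, s12], [s12, s12, s11]]
        )
        eps = rng.multivariate_normal(np.zeros(3), cov, size=n, method="cholesky")
        series = StrainSeries(time, eps, np.full(3, V0 ** (1.0 / 3.0)), T)
        y_mpa = young_from_constants(c11, c12) / 1e6
        report = GeneratorReport(
            "fluctuations_strain", seed,
            planted={"C11_GPa": C11, "C12_GPa": C12, "V0_A3": V0, "T_K": T, "n": n},
            truth={"C11_GPa": C11, "C12_GPa": C12,
                   "B_GPa": (C11 + 2 * C12) / 3.0, "Y_MPa": y_mpa},
        )
        return series, report
    raise ValueError(f"unknown fluctuation kind {kind!r}")


def gen_stress_strain(
    a: float = 0.014381,
    b: float = 0.50677,
    sigma_grid: np.ndarray | None = None,
    noise: float = 0.02,
    seed: int = 0,
) -> tuple[pd.DataFrame, GeneratorReport]:
    """Nonlinear stress-strain points f(sigma) = a*sigma/(1 - b*sigma).

    ``a`` in 1/MPa, ``b`` in 1/MPa; multiplicative Gaussian noise of the
    given relative size.  The planted truth is Y(sigma) = (1 - b*sigma)^2/a
    on the grid.  The default constants give Y(0.3 MPa) = 50 MPa and
    Y(1.5 MPa) = 4 MPa.
    """
    if sigma_grid is None:
        sigma_grid = np.linspace(0.1, 1.5, 15)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if np.any(1.0 - b * sigma_grid <= 0.0):
        raise ValueError("pole of the planted curve inside the stress grid")
    rng = np.random.default_rng(seed)
    f = a * sigma_grid / (1.0 - b * sigma_grid)
    noisy = f * (1.0 + rng.normal(0.0, noise, size=f.shape)) if noise > 0 else f
    se = np.abs(f) * noise if noise > 0 else None
    df = pd.DataFrame({
        "stress_MPa": sigma_grid,
        "strain": noisy,
        "strain_se": se if se is not None else 0.0,
    })
    report = GeneratorReport(
        "stress_strain", seed,
        planted={"a_per_MPa": a, "b_per_MPa": b, "noise": noise,
                 "n_points": len(sigma_grid)},
        truth={"Y_MPa": {f"{s:g}": (1.0 - b * s) ** 2 / a for s in sigma_grid}},
    )
    return df, report


# ---------------------------------------------------------------------------
# random-walk water
# ---------------------------------------------------------------------------

def gen_random_walk(
    D: float,
    dt: float = 1.0,
    n_particles: int = 1000,
    n_steps: int = 1000,
    box: BoxDims | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GeneratorReport]:
    """3-D random walks with planted diffusion constant D.

    Per-step displacements are Gaussian with variance 2*D*dt per dimension,
    so MSD(t) = 6*D*t.  Returns (unwrapped, wrapped, report); positions
    have shape (n_steps + 1, n_particles, 3).
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if box is None:
        box = BoxDims(100.0, 100.0, 100.0)
    rng = np.random.default_rng(seed)
    start = rng.uniform(0.0, box.lengths, size=(n_particles, 3))
    steps = rng.normal(0.0, np.sqrt(2.0 * D * dt), size=(n_steps, n_particles, 3))
    unwrapped = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    wrapped = np.mod(unwrapped, box.lengths)
    report = GeneratorReport(
        "random_walk", seed,
        planted={"D": D, "dt": dt, "n_particles": n_particles, "n_steps": n_steps},
        truth={"D": D},
    )
    return unwrapped, wrapped, report


# ---------------------------------------------------------------------------
# point configurations for S(k) validation
# ---------------------------------------------------------------------------

def gen_point_configs(
    kind: str,
    *,
    n: int = 10_000,
    box: BoxDims | None = None,
    lattice_a: float = 5.37,
    cluster_radius: float = 10.0,
    cluster_spacing: float = 105.0,
    n_frames: int = 1,
    seed: int = 0,
) -> tuple[list[np.ndarray], BoxDims, GeneratorReport]:
    """Point configurations with known structure-factor features.

    ``uniform``: ideal gas, S(k) = 1.  ``lattice``: simple cubic with
    spacing ``lattice_a`` -> Bragg peak at 2*pi/a.  ``clusters``: Gaussian
    blobs of radius ``cluster_radius`` on a cubic grid of spacing
    ``cluster_spacing`` -> low-k peak near 2*pi/spacing.
    """
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        if n < 100:
            raise ValueError("need at least 100 points")
        box = box or BoxDims(200.0, 200.0, 200.0)
        frames = [rng.uniform(0, box.lengths, size=(n, 3)) for _ in range(n_frames)]
        truth = {"S": 1.0}
    elif kind == "lattice":
        m = max(2, int(round(n ** (1.0 / 3.0))))
        side = m * lattice_a
        box = BoxDims(side, side, side)
        g = np.arange(m) * lattice_a
        pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
        frames = [pts for _ in range(n_frames)]
        truth = {"bragg_k": 2.0 * np.pi / lattice_a, "n_points": len(pts)}
    elif kind == "clusters":
        box = box or BoxDims(500.0, 500.0, 500.0)
        m = int(box.lengths[0] // cluster_spacing)
        g = (np.arange(m) + 0.5) * cluster_spacing
        centers = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)
        per = max(1, n // len(centers))
        frames = []
        for _ in range(n_frames):
            pts = centers[:, None, :] + rng.normal(
                0.0, cluster_radius, size=(len(centers), per, 3)
            )
            frames.append(np.mod(pts.reshape(-1, 3), box.lengths))
        truth = {"peak_k": 2.0 * np.pi / cluster_spacing}
    else:
        raise ValueError(f"unknown configuration kind {kind!r}")
    report = GeneratorReport(
        f"points_{kind}", seed,
        planted={"kind": kind, "n": n, "n_frames": n_frames},
        truth=truth,
    )
    return frames, box, report


# ---------------------------------------------------------------------------
# diffractograms
# ---------------------------------------------------------------------------

def gen_diffractogram(
    cri_planted: float,
    template: list[PeakTemplate] | None = None,
    noise: float = 0.01,
    seed: int = 0,
    step: float = 0.10,
    background: tuple[float, float] = (40.0, -0.5),
) -> tuple[Diffractogram, GeneratorReport]:
    """Synthetic diffractogram with a planted crystalline/total area ratio.

    Template peak areas are rescaled so the crystalline fraction of the
    total peak area equals ``cri_planted`` percent; a linear background and
    multiplicative Gaussian noise are added.
    """
    if not 0.0 < cri_planted < 100.0:
        raise ValueError("planted CrI must be in (0, 100)")
    if template is None:
        template = cellulose_template()
    rng = np.random.default_rng(seed)
    x = np.arange(10.0, 40.0 + step / 2, step)

    cryst_area = sum(t.area for t in template if t.crystalline)
    amorph_area = sum(t.area for t in template if not t.crystalline)
    if cryst_area <= 0 or amorph_area <= 0:
        raise ValueError("template needs both crystalline and amorphous peaks")
    f = cri_planted / 100.0
    scale_c = f / cryst_area
    scale_a = (1.0 - f) / amorph_area
    total = 1000.0  # overall intensity scale, counts
    y = background[0] + background[1] * (x - x[0])
    for t in template:
        area = total * t.area * (scale_c if t.crystalline else scale_a)
        y = y + _gaussian(x, area, t.center, t.fwhm / (2 * np.sqrt(2 * np.log(2))))
    if noise > 0:
        y = y * (1.0 + rng.normal(0.0, noise, size=y.shape))
    y = np.clip(y, 0.0, None)
    report = GeneratorReport(
        "diffractogram", seed,
        planted={"CrI_pct": cri_planted, "noise": noise, "step_deg": step},
        truth={"CrI_pct": cri_planted},
    )
    return Diffractogram(x, y), report


# ---------------------------------------------------------------------------
# hydrogen-bond fixture
# ---------------------------------------------------------------------------

def gen_hb_fixture(
    n_true: int,
    n_decoy: int,
    seed: int = 0,
    d_max: float = 3.2,
    ang_max: float = 40.0,
) -> tuple[Frame, Topology, GeneratorReport]:
    """O-H...O triples: ``n_true`` satisfy both hydrogen-bond criteria,
    ``n_decoy`` violate exactly one each (half distance, half angle).

    Triples are isolated on a coarse grid so no accidental cross-triple
    bonds arise; criteria are strict inequalities and the generator keeps
    a margin away from the boundaries.
    """
    if n_true < 0 or n_decoy < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    n_total = n_true + n_decoy
    cell = 16.0  # isolates triples: worst-case cross-triple O-O is > 4.5 A
    m = max(1, int(np.ceil(n_total ** (1.0 / 3.0))))
    box = BoxDims(m * cell, m * cell, m * cell)

    kinds = ["true"] * n_true + ["decoy_d"] * (n_decoy // 2) + \
            ["decoy_a"] * (n_decoy - n_decoy // 2)
    positions, names, rows, bonds = [], [], [], []

    for t_idx, kind in enumerate(kinds):
        i, j, k = np.unravel_index(t_idx, (m, m, m))
        origin = (np.array([i, j, k]) + 0.5) * cell
        if kind == "true":
            dist = rng.uniform(2.7, d_max - 0.1)
            dev = rng.uniform(0.0, ang_max - 3.0)
        elif kind == "decoy_d":
            dist = rng.uniform(d_max + 0.1, 4.5)
            dev = rng.uniform(0.0, ang_max - 3.0)
        else:
            dist = rng.uniform(2.7, d_max - 0.1)
            dev = rng.uniform(ang_max + 5.0, 90.0)
        o_d = origin
        h = origin + np.array([0.96, 0.0, 0.0])
        # acceptor direction from H at 'dev' degrees off the O->H axis
        theta = np.deg2rad(dev)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        # solve |h + r*u - o_d| = dist for r > 0
        w = h - o_d
        b_coef = 2.0 * np.dot(w, u)
        c_coef = np.dot(w, w) - dist**2
        r = (-b_coef + np.sqrt(b_coef**2 - 4.0 * c_coef)) / 2.0
        o_a = h + r * u
        base = len(positions)
        positions += [o_d, h, o_a]
        names += ["O2", "HO2", "O3"]
        for a_off, (nm, el) in enumerate(
            zip(["O2", "HO2", "O3"], ["O", "H", "O"])
        ):
            rows.append({
                "atom_index": base + a_off, "element": el, "name": nm,
                "species": "cellulose", "unit_kind": "cellulose_chain",
                "unit_id": t_idx, "chain_id": 0, "ring_index": 0,
                "donor_flag": nm in ("O2", "HO2"),
                "acceptor_flag": el == "O",
            })
        bonds.append((base, base + 1))

    pos = np.asarray(positions).reshape(-1, 3)
    frame = Frame(box, pos, [r["name"] for r in rows], [r["element"] for r in rows])
    topo = Topology(
        pd.DataFrame(rows, columns=TOPOLOGY_COLUMNS),
        oh_bonds=np.array(bonds, dtype=int).reshape(-1, 2),
    )
    report = GeneratorReport(
        "hb_fixture", seed,
        planted={"n_true": n_true, "n_decoy": n_decoy},
        truth={"n_hbonds": n_true},
    )
    return frame, topo, report


# ---------------------------------------------------------------------------
# freely-jointed chains (end-to-end statistics oracle input)
# ---------------------------------------------------------------------------

def gen_fjc_chains(
    n_chains: int, n_bonds: int = 46, bond_length: float = 5.2, seed: int = 0
) -> tuple[np.ndarray, GeneratorReport]:
    """End-to-end distances of ideal freely-jointed chains.

    <l^2> = n_bonds * bond_length^2 exactly; the radial density of l is the
    closed-form FJC distribution.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_chains, n_bonds, 3))
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    ends = bond_length * v.sum(axis=1)
    l = np.linalg.norm(ends, axis=-1)
    report = GeneratorReport(
        "fjc_chains", seed,
        planted={"n_chains": n_chains, "n_bonds": n_bonds, "b": bond_length},
        truth={"mean_sq_l": n_bonds * bond_length**2},
    )
    return l, report
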