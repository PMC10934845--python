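"""Periodic-boundary geometry, unwrapping, and trajectory I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from glucangel.builder import build_chain, ATOMS_PER_RING
from glucangel.core import (
    BoxDims,
    Frame,
    Topology,
    TOPOLOGY_COLUMNS,
    minimum_image_displacement,
    minimum_image_distance,
    unwrap_chain,
    wrap_positions,
)
from glucangel.io import ParseError, read_topology, read_trajectory, write_topology, write_trajectory


def brute_force_min_image(a, b, box):
    """Oracle: minimum distance over all 27 neighbor images."""
    L = box.lengths
    best = np.inf
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                d = np.linalg.norm(b + np.array([i, j, k]) * L - a)
                best = min(best, d)
    return best


class TestMinimumImage:
    def test_wraparound(self):
        box = BoxDims(10, 10, 10)
        d = minimum_image_distance(np.zeros(3), np.array([9.0, 0, 0]), box)
        assert d == pytest.approx(1.0)

    def test_identity(self):
        box = BoxDims(10, 10, 10)
        a = np.array([3.0, 4.0, 5.0])
        assert minimum_image_distance(a, a, box) == 0.0

    def test_components_in_half_open_interval(self):
        box = BoxDims(8, 9, 10)
        rng = np.random.default_rng(0)
        a = rng.uniform(-20, 20, size=(500, 3))
        b = rng.uniform(-20, 20, size=(500, 3))
        d = minimum_image_displacement(a, b, box)
        L = box.lengths
        assert np.all(d > -L / 2) and np.all(d <= L / 2)

    def test_matches_27_image_brute_force(self):
        box = BoxDims(12, 15, 9)
        rng = np.random.default_rng(42)
        a = rng.uniform(0, box.lengths, size=(1000, 3))
        b = rng.uniform(0, box.lengths, size=(1000, 3))
        fast = minimum_image_distance(a, b, box)
        for i in range(1000):
            assert fast[i] == pytest.approx(
                brute_force_min_image(a[i], b[i], box), abs=1e-10
            )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6))
    def test_translation_invariance(self, coords):
        box = BoxDims(11.0, 13.0, 7.0)
        a = np.array(coords[:3])
        b = np.array(coords[3:])
        shift = np.array([3.7, -1.2, 9.9])
        d1 = minimum_image_distance(a, b, box)
        d2 = minimum_image_distance(a + shift, b + shift, box)
        assert d1 == pytest.approx(d2, abs=1e-9)


def _chain_frame(chain, box, shift=(0.0, 0.0, 0.0), wrap=True):
    """Frame + topology for one chain placed in a box."""
    pos = chain.positions + np.asarray(shift)
    truth = pos.copy()
    if wrap:
        pos = wrap_positions(pos, box)
    tab = pd.DataFrame({
        "atom_index": np.arange(chain.n_atoms),
        "element": chain.elements,
        "name": chain.names,
        "species": chain.species,
        "unit_kind": "cellulose_chain",
        "unit_id": 0,
        "chain_id": 0,
        "ring_index": chain.ring_index,
        "donor_flag": False,
        "acceptor_flag": False,
    })
    frame = Frame(box, pos, chain.names, chain.elements)
    return frame, Topology(tab, oh_bonds=chain.oh_bonds), truth


class TestUnwrap:
    def test_chain_crossing_face_exceeds_box(self):
        box = BoxDims(30.0, 30.0, 30.0)
        chain = build_chain("cellulose", 10)  # 10 rings along z, ~49 A
        frame, topo, _ = _chain_frame(chain, box, shift=(5, 5, 10))
        out = unwrap_chain(frame, topo, 0)
        assert np.ptp(out[:, 2]) > 30.0
        cents = [
            out[k * ATOMS_PER_RING: k * ATOMS_PER_RING + 6, 2].mean()
            for k in range(10)
        ]
        assert np.all(np.diff(cents) > 0)  # monotone along the chain axis

    def test_identity_when_inside_box(self):
        box = BoxDims(300.0, 300.0, 300.0)
        chain = build_chain("cellulose", 5)
        frame, topo, truth = _chain_frame(chain, box, shift=(100, 100, 100))
        out = unwrap_chain(frame, topo, 0)
        np.testing.assert_allclose(out, truth, atol=1e-10)

    def test_wrapped_helix_recovers_true_end_to_end(self):
        box = BoxDims(25.0, 25.0, 25.0)
        chain = build_chain("callose", 20, "helical")  # axial extent 57 A, wraps twice
        frame, topo, truth = _chain_frame(chain, box, shift=(10, 10, 3))
        out = unwrap_chain(frame, topo, 0)
        ring = lambda xyz, k: xyz[k * ATOMS_PER_RING: k * ATOMS_PER_RING + 6].mean(axis=0)
        e2e_true = np.linalg.norm(ring(truth, 19) - ring(truth, 0))
        e2e_unwrapped = np.linalg.norm(ring(out, 19) - ring(out, 0))
        assert e2e_unwrapped == pytest.approx(e2e_true, abs=1e-6)

    def test_unwrap_then_rewrap_is_identity(self):
        box = BoxDims(30.0, 30.0, 30.0)
        chain = build_chain("cellulose", 12)
        frame, topo, _ = _chain_frame(chain, box, shift=(3, 3, 12))
        out = unwrap_chain(frame, topo, 0)
        np.testing.assert_allclose(
            wrap_positions(out, box), frame.positions, atol=1e-9
        )


class TestTrajectoryIO:
    def test_gro_nm_to_angstrom(self, tmp_path):
        p = tmp_path / "two.gro"
        p.write_text(
            "frame t= 0.0\n"
            "    3\n"
            "    1MOL    OW    1   0.100   0.200   0.300\n"
            "    1MOL   HW1    2   0.150   0.200   0.300\n"
            "    1MOL   HW2    3   0.100   0.260   0.300\n"
            "   2.50000   2.50000   2.50000\n"
            "frame t= 1.0\n"
            "    3\n"
            "    1MOL    OW    1   0.110   0.200   0.300\n"
            "    1MOL   HW1    2   0.160   0.200   0.300\n"
            "    1MOL   HW2    3   0.110   0.260   0.300\n"
            "   2.50000   2.50000   2.50000\n"
        )
        frames = read_trajectory(p)
        assert len(frames) == 2
        assert frames[0].box.Lx == pytest.approx(25.0)
        assert frames[0].positions[0, 0] == pytest.approx(1.0)
        assert frames[1].time == pytest.approx(1.0)

    @pytest.mark.parametrize("fmt", ["gro", "xyz", "pdb"])
    def test_round_trip(self, tmp_path, fmt, rng):
        box = BoxDims(20.0, 25.0, 30.0)
        pos = rng.uniform(0, 19, size=(2, 7, 3))
        frames = [
            Frame(box, pos[t], ["OW"] * 7, ["O"] * 7, time=float(t))
            for t in range(2)
        ]
        p = tmp_path / f"traj.{fmt}"
        write_trajectory(p, frames)
        back = read_trajectory(p)
        assert len(back) == 2
        # declared precision: GRO 1e-3 nm = 1e-2 A; XYZ/PDB 1e-3 A
        tol = 1.1e-2 if fmt == "gro" else 1.1e-3
        for fr, fb in zip(frames, back):
            np.testing.assert_allclose(fb.positions, fr.positions, atol=tol)
            np.testing.assert_allclose(fb.box.lengths, fr.box.lengths, atol=1e-3)

    def test_gro_agrees_with_mdanalysis_reader(self, tmp_path, rng):
        import MDAnalysis as mda

        box = BoxDims(20.0, 20.0, 20.0)
        pos = rng.uniform(1, 19, size=(5, 3))
        frame = Frame(box, pos, ["C1"] * 5, ["C"] * 5)
        p = tmp_path / "one.gro"
        write_trajectory(p, [frame])
        u = mda.Universe(str(p))
        np.testing.assert_allclose(u.atoms.positions, pos, atol=1.1e-2)
        np.testing.assert_allclose(u.dimensions[:3], box.lengths, atol=1e-3)

    def test_xyz_missing_coordinate_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\nbox 10 10 10\nC 1.0 2.0 3.0\nO 1.0 2.0\n")
        with pytest.raises(ParseError, match="bad.xyz:4"):
            read_trajectory(p)

    def test_gro_missing_box_is_error(self, tmp_path):
        p = tmp_path / "nobox.gro"
        p.write_text("t\n    1\n    1MOL    OW    1   0.1   0.2   0.3\n")
        with pytest.raises(ParseError, match="box"):
            read_trajectory(p)

    def test_triclinic_box_rejected(self, tmp_path):
        p = tmp_path / "tri.gro"
        p.write_text(
            "t\n    1\n    1MOL    OW    1   0.100   0.200   0.300\n"
            "   2.5   2.5   2.5   0.0   0.0   1.2   0.0   0.0   0.0\n"
        )
        with pytest.raises(ValueError, match="triclinic"):
            read_trajectory(p)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_trajectory("/nonexistent/x.gro")


class TestTopologySidecar:
    def test_round_trip_with_bond_inference(self, tmp_path):
        chain = build_chain("cellulose", 3)
        tab = pd.DataFrame({
            "atom_index": np.arange(chain.n_atoms),
            "element": chain.elements,
            "name": chain.names,
            "species": "cellulose",
            "unit_kind": "cellulose_chain",
            "unit_id": 7,
            "chain_id": 0,
            "ring_index": chain.ring_index,
            "donor_flag": [n.startswith("HO") for n in chain.names],
            "acceptor_flag": [e == "O" for e in chain.elements],
        })
        topo = Topology(tab, oh_bonds=chain.oh_bonds, meta={"sample": "t", "seed": 3})
        p = tmp_path / "x.top.tsv"
        write_topology(p, topo)
        back = read_topology(p)
        assert back.meta == {"sample": "t", "seed": 3}
        pd.testing.assert_frame_equal(
            back.table[TOPOLOGY_COLUMNS], topo.table[TOPOLOGY_COLUMNS]
        )
        # bond inference recovers the builder's covalent O-H pairs
        assert set(map(tuple, back.oh_bonds)) == set(map(tuple, topo.oh_bonds))

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.top.tsv"
        p.write_text("atom_index\telement\n1\tO\n")
        with pytest.raises(ParseError, match="missing columns"):
            read_topology(p)


def test_box_must_be_positive():
    with pytest.raises(ValueError):
        BoxDims(0.0, 10.0, 10.0)
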