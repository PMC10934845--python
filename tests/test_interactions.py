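"""Hydrogen-bond criteria, contact detection, link clustering, network stats."""

import numpy as np
import pandas as pd
import pytest

from glucangel.core import BoxDims, Frame, Topology, minimum_image_displacement
from glucangel.interactions import (
    HB_CLASSES,
    HBond,
    Link,
    cluster_links,
    detect_hbonds,
    network_stats,
    short_contacts,
    tally_hbonds,
)
from glucangel.synthetic import gen_crossing_fixture, gen_hb_fixture


def brute_force_hbonds(frame, topology, d_max=3.2, ang_max=40.0):
    """Oracle: triple loop over every donor O-H group x every acceptor O."""
    tab = topology.table
    acceptors = tab.index[tab["element"] == "O"].to_numpy()
    box = frame.box
    found = []
    for o_i, h_i in topology.oh_bonds:
        for a_i in acceptors:
            if a_i == o_i:
                continue
            d = np.linalg.norm(
                minimum_image_displacement(
                    frame.positions[o_i], frame.positions[a_i], box)
            )
            u = minimum_image_displacement(
                frame.positions[h_i], frame.positions[o_i], box)
            v = minimum_image_displacement(
                frame.positions[h_i], frame.positions[a_i], box)
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            dev = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if d < d_max and dev < ang_max:
                found.append((int(o_i), int(h_i), int(a_i)))
    return sorted(found)


def triple_frame(d_oo, dev_deg, box_side=50.0):
    """One O-H...O triple with given O-O distance and linearity deviation."""
    o_d = np.array([10.0, 10.0, 10.0])
    h = o_d + np.array([0.96, 0.0, 0.0])
    theta = np.deg2rad(dev_deg)
    u = np.array([np.cos(theta), np.sin(theta), 0.0])
    w = h - o_d
    b = 2 * np.dot(w, u)
    c = np.dot(w, w) - d_oo**2
    r = (-b + np.sqrt(b * b - 4 * c)) / 2
    o_a = h + r * u
    pos = np.array([o_d, h, o_a])
    names = ["O2", "HO2", "O3"]
    tab = pd.DataFrame({
        "atom_index": [0, 1, 2],
        "element": ["O", "H", "O"],
        "name": names,
        "species": "cellulose",
        "unit_kind": "cellulose_chain",
        "unit_id": [0, 0, 1],
        "chain_id": 0,
        "ring_index": 0,
        "donor_flag": [True, True, False],
        "acceptor_flag": [True, False, True],
    })
    frame = Frame(BoxDims(box_side, box_side, box_side), pos, names, ["O", "H", "O"])
    return frame, Topology(tab, oh_bonds=np.array([[0, 1]]))


class TestHBondCriteria:
    def test_good_geometry_is_one_bond(self):
        frame, topo = triple_frame(3.0, 10.0)
        bonds = detect_hbonds(frame, topo)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(3.0)
        assert bonds[0].deviation_deg == pytest.approx(10.0, abs=1e-6)

    def test_distance_beyond_cutoff_fails(self):
        frame, topo = triple_frame(3.3, 10.0)
        assert detect_hbonds(frame, topo) == []

    def test_angle_beyond_cutoff_fails(self):
        frame, topo = triple_frame(3.0, 55.0)
        assert detect_hbonds(frame, topo) == []

    def test_distance_boundary_is_strict(self):
        # collinear triple with O-O exactly 3.2 (donor O at the origin keeps
        # the displacement exactly representable)
        frame, topo = triple_frame(3.0, 0.0)
        frame.positions[0] = np.array([0.0, 10.0, 10.0])
        frame.positions[1] = np.array([0.96, 10.0, 10.0])
        frame.positions[2] = np.array([3.2, 10.0, 10.0])
        assert detect_hbonds(frame, topo) == []
        frame.positions[2] = np.array([3.1999, 10.0, 10.0])
        assert len(detect_hbonds(frame, topo)) == 1

    def test_angle_boundary_is_strict(self):
        frame, topo = triple_frame(3.0, 40.001)
        assert detect_hbonds(frame, topo) == []

    def test_no_hydrogens_is_error(self):
        frame, topo = triple_frame(3.0, 10.0)
        topo.oh_bonds = np.empty((0, 2), dtype=int)
        with pytest.raises(ValueError, match="no O-H"):
            detect_hbonds(frame, topo)

    def test_planted_fixture_matches_brute_force(self):
        frame, topo, rep = gen_hb_fixture(10, 20, seed=8)
        fast = detect_hbonds(frame, topo)
        assert len(fast) == rep.truth["n_hbonds"] == 10
        oracle = brute_force_hbonds(frame, topo)
        got = sorted((b.donor_oxygen, b.hydrogen, b.acceptor_oxygen) for b in fast)
        assert got == oracle

    @pytest.mark.parametrize("seed", range(5))
    def test_recovery_across_seeds(self, seed):
        frame, topo, rep = gen_hb_fixture(7, 14, seed=seed)
        assert len(detect_hbonds(frame, topo)) == 7

    def test_empty_fixture(self):
        frame, topo, _ = gen_hb_fixture(0, 50, seed=1)
        assert detect_hbonds(frame, topo) == []


class TestTally:
    def _hb(self, cls):
        return HBond(0, 1, 2, 3.0, 5.0, cls)

    def test_constructed_tallies(self):
        bonds = [self._hb("cellulose-cellulose intra")] * 3 + \
                [self._hb("cellulose-water")] * 2
        counts = tally_hbonds(bonds)
        assert counts["cellulose-cellulose intra"] == 3
        assert counts["cellulose-water"] == 2
        assert sum(counts.values()) == 5
        assert set(counts) == set(HB_CLASSES)

    def test_empty_is_all_zero(self):
        counts = tally_hbonds([])
        assert all(v == 0 for v in counts.values())

    def test_classes_conserve_totals(self, rng):
        bonds = [self._hb(rng.choice(HB_CLASSES)) for _ in range(200)]
        assert sum(tally_hbonds(bonds).values()) == 200

    def test_unknown_class_is_error(self):
        with pytest.raises(ValueError):
            tally_hbonds([self._hb("cellulose-starch")])


def parallel_chain_frame(gap, same_unit=False, n_atoms=10, spacing=5.0):
    """Two straight 'chains' of single pseudo-atoms, a fixed gap apart."""
    z = np.arange(n_atoms) * spacing
    a = np.column_stack([np.full(n_atoms, 20.0), np.full(n_atoms, 20.0), z + 5])
    b = a + np.array([gap, 0.0, 0.0])
    pos = np.vstack([a, b])
    n = 2 * n_atoms
    tab = pd.DataFrame({
        "atom_index": np.arange(n),
        "element": "C",
        "name": "C1",
        "species": "cellulose",
        "unit_kind": "cellulose_chain" if not same_unit else "nanofiber",
        "unit_id": [0] * n_atoms + ([0] if same_unit else [1]) * n_atoms,
        "chain_id": [0] * n_atoms + [1] * n_atoms,
        "ring_index": list(range(n_atoms)) * 2,
        "donor_flag": False,
        "acceptor_flag": False,
    })
    frame = Frame(BoxDims(60, 60, 60), pos, ["C1"] * n, ["C"] * n)
    return frame, Topology(tab)


class TestShortContacts:
    def test_parallel_chains_within_cutoff(self):
        frame, topo = parallel_chain_frame(3.0)
        contacts = short_contacts(frame, topo)
        assert len(contacts) == 10  # each atom pairs with its opposite only
        # O(N^2) oracle
        d = np.linalg.norm(
            frame.positions[:, None, :] - frame.positions[None, :, :], axis=-1
        )
        brute = sum(
            1 for i in range(10) for j in range(10, 20) if d[i, j] < 3.6
        )
        assert len(contacts) == brute

    def test_distant_chains_have_none(self):
        frame, topo = parallel_chain_frame(5.0)
        assert short_contacts(frame, topo).empty

    def test_intrafiber_pairs_excluded(self):
        frame, topo = parallel_chain_frame(3.0, same_unit=True)
        assert short_contacts(frame, topo).empty

    def test_hydrogens_excluded(self):
        frame, topo = parallel_chain_frame(3.0)
        topo.table["element"] = "H"
        assert short_contacts(frame, topo).empty


def contact_table(rows):
    return pd.DataFrame(
        rows, columns=["i", "j", "distance", "unit_i", "unit_j",
                       "chain_i", "chain_j", "ring_i", "ring_j"]
    )


def two_unit_topology():
    tab = pd.DataFrame({
        "atom_index": [0, 1],
        "element": ["C", "C"],
        "name": "C1",
        "species": "cellulose",
        "unit_kind": "cellulose_chain",
        "unit_id": [0, 1],
        "chain_id": 0,
        "ring_index": 0,
        "donor_flag": False,
        "acceptor_flag": False,
    })
    return Topology(tab)


class TestClusterLinks:
    def test_single_crossing_is_one_link(self):
        topo = two_unit_topology()
        c = contact_table([
            (0, 1, 3.0, 0, 1, 0, 0, 10, 3),
            (0, 1, 3.1, 0, 1, 0, 0, 11, 4),
        ])
        links = cluster_links(c, topo)
        assert len(links) == 1 and links[0].nc == 2
        assert links[0].ring_span_a == (10, 11)

    def test_two_crossings_far_apart_are_two_links(self):
        topo = two_unit_topology()
        c = contact_table([
            (0, 1, 3.0, 0, 1, 0, 0, 10, 3),
            (0, 1, 3.0, 0, 1, 0, 0, 30, 23),
        ])
        assert len(cluster_links(c, topo)) == 2

    def test_contact_order_invariance(self, rng):
        topo = two_unit_topology()
        rows = [(0, 1, 3.0, 0, 1, 0, 0, int(r), int(r) // 2)
                for r in rng.integers(0, 40, size=30)]
        base = cluster_links(contact_table(rows), topo)
        perm = cluster_links(
            contact_table([rows[i] for i in rng.permutation(30)]), topo)
        key = lambda links: sorted((l.nc, l.ring_span_a, l.ring_span_b) for l in links)
        assert key(base) == key(perm)

    def test_matches_union_find_oracle(self, rng):
        topo = two_unit_topology()
        rows = [
            (0, 1, 3.0, 0, 1, 0, 0, int(ra), int(rb))
            for ra, rb in rng.integers(0, 25, size=(40, 2))
        ]
        links = cluster_links(contact_table(rows), topo, ring_window=2)

        # independent union-find
        parent = list(range(40))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for p in range(40):
            for q in range(p + 1, 40):
                if abs(rows[p][7] - rows[q][7]) <= 2 and \
                   abs(rows[p][8] - rows[q][8]) <= 2:
                    parent[find(p)] = find(q)
        n_clusters = len({find(x) for x in range(40)})
        assert len(links) == n_clusters
        assert sorted(l.nc for l in links) == sorted(
            np.bincount([find(x) for x in range(40)])[
                np.bincount([find(x) for x in range(40)]) > 0]
        )

    def test_empty_contacts(self):
        assert cluster_links(contact_table([]), two_unit_topology()) == []


def star_topology(n_chains):
    rows = []
    rows.append(dict(atom_index=0, element="C", name="C1", species="cellulose",
                     unit_kind="nanofiber", unit_id=0, chain_id=0, ring_index=0,
                     donor_flag=False, acceptor_flag=False))
    for u in range(1, n_chains + 1):
        rows.append(dict(atom_index=u, element="C", name="C1", species="cellulose",
                         unit_kind="cellulose_chain", unit_id=u, chain_id=0,
                         ring_index=0, donor_flag=False, acceptor_flag=False))
    return Topology(pd.DataFrame(rows))


def mk_link(a, b, ka, kb):
    return Link(a, b, ka, kb, contacts=pd.DataFrame(), nc=1)


class TestNetworkStats:
    def test_star_fixture(self):
        topo = star_topology(4)
        links = [mk_link(0, u, "nanofiber", "cellulose_chain") for u in range(1, 5)]
        st = network_stats(links, topo)
        assert st["n_links"] == 4
        assert st["n_components"] == 1
        assert st["isolated_units"] == []
        assert st["fiber_fiber_links"] == 0
        assert st["avg_links_per_cellulose_chain"] == 1.0

    def test_disjoint_pairs_are_two_components(self):
        topo = star_topology(4)  # units 0..4; use 1-2 and 3-4
        links = [
            mk_link(1, 2, "cellulose_chain", "cellulose_chain"),
            mk_link(3, 4, "cellulose_chain", "cellulose_chain"),
        ]
        st = network_stats(links, topo)
        assert st["n_components"] == 3  # two pairs + the untouched fiber
        assert st["isolated_units"] == [0]

    def test_degree_recount_oracle(self, rng):
        topo = star_topology(6)
        pairs = rng.integers(0, 7, size=(20, 2))
        links = [mk_link(int(a), int(b), "cellulose_chain", "cellulose_chain")
                 for a, b in pairs if a != b]
        st = network_stats(links, topo)
        degree = {u: 0 for u in range(7)}
        for l in links:
            degree[l.unit_a] += 1
            degree[l.unit_b] += 1
        assert st["links_per_unit"] == degree


class TestPlantedCrossings:
    def test_exact_link_recovery(self, crossing_fixture):
        """Five planted chain-fiber crossings at 3.0 A give exactly 5 links."""
        frame, topo, rep = crossing_fixture
        contacts = short_contacts(frame, topo)
        links = cluster_links(contacts, topo)
        assert len(links) == rep.truth["n_links"] == 5
        for l in links:
            assert {l.kind_a, l.kind_b} == {"nanofiber", "cellulose_chain"}

    def test_network_is_fully_bridged(self):
        """Chains bridge the fibers: no fiber-fiber links, no floating
        chains, one connected component -- as in the hydrogel picture."""
        frame, topo, rep = gen_crossing_fixture(n_chains=4, n_fibers=2, seed=9)
        links = cluster_links(short_contacts(frame, topo), topo)
        st = network_stats(links, topo)
        assert st["fiber_fiber_links"] == 0
        assert st["isolated_units"] == []
        assert st["n_components"] == 1
        assert st["avg_links_per_cellulose_chain"] == 2.0
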