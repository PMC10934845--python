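"""Hydrogen-bond detection, interunit short contacts, link clustering and
network connectivity statistics.

A hydrogen bond is geometric: an O-H...O triple whose O-O distance is below
3.2 A and whose O-H-O angle deviates from linearity by less than 40
degrees.  A *link* is a localized cluster of interunit atom contacts closer
than 3.6 A between two separate polysaccharide units (nanofibers or single
chains); contacts inside one unit -- in particular the extensive chain-chain
contacts within a crystalline nanofiber -- do not count.  Contact counts of
a single link (nc) are of order tens for chain crossings and can reach
hundreds for coiled chain pairs.

Neighbor searches use periodic KD-trees with cell edge equal to the cutoff;
tests require exact equivalence with the O(N^2) brute force.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .core import BoxDims, Frame, Topology, minimum_image_displacement, wrap_positions

__all__ = [
    "HBond",
    "Link",
    "detect_hbonds",
    "tally_hbonds",
    "short_contacts",
    "cluster_links",
    "network_stats",
    "HB_CLASSES",
]

HB_CLASSES = (
    "cellulose-cellulose intra",
    "cellulose-cellulose inter",
    "callose-callose intra",
    "callose-callose inter",
    "cellulose-callose",
    "cellulose-water",
    "callose-water",
    "water-water",
)


@dataclass(frozen=True)
class HBond:
    donor_oxygen: int
    hydrogen: int
    acceptor_oxygen: int
    distance: float          # O-O, angstroms
    deviation_deg: float     # O-H-O deviation from linearity
    hb_class: str


@dataclass
class Link:
    unit_a: int
    unit_b: int
    kind_a: str
    kind_b: str
    contacts: pd.DataFrame = field(repr=False)  # rows of the contact table
    nc: int = 0
    ring_span_a: tuple[int, int] = (0, 0)
    ring_span_b: tuple[int, int] = (0, 0)


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    d_max: float = 3.2,
    ang_max: float = 40.0,
) -> list[HBond]:
    """All O-H...O hydrogen bonds under the geometric criteria (strict <).

    Donor groups are the covalent O-H pairs of the topology; every oxygen is
    a potential acceptor.  Distances use the minimum image convention.
    One record is produced per (hydrogen, acceptor) pair.
    """
    topology.validate_against(frame)
    if topology.oh_bonds.shape[0] == 0:
        raise ValueError("topology contains no O-H groups: criteria inapplicable")
    tab = topology.table
    acceptors = tab.index[tab["element"] == "O"].to_numpy()
    if acceptors.size == 0:
        return []
    box = frame.box
    pos = frame.positions
    acc_pos = wrap_positions(pos[acceptors], box)
    tree = cKDTree(acc_pos, boxsize=box.lengths)

    species = tab["species"].to_numpy()
    unit_id = tab["unit_id"].to_numpy()
    chain_id = tab["chain_id"].to_numpy()

    out: list[HBond] = []
    don_o = topology.oh_bonds[:, 0]
    don_h = topology.oh_bonds[:, 1]
    don_pos = wrap_positions(pos[don_o], box)
    neigh = tree.query_ball_point(don_pos, r=d_max)
    for (o_i, h_i, cand) in zip(don_o, don_h, neigh):
        for j in cand:
            a_i = int(acceptors[j])
            if a_i == o_i:
                continue
            d = np.linalg.norm(minimum_image_displacement(pos[o_i], pos[a_i], box))
            if not d < d_max:
                continue
            u = minimum_image_displacement(pos[h_i], pos[o_i], box)
            v = minimum_image_displacement(pos[h_i], pos[a_i], box)
            cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            dev = 180.0 - ang
            if not dev < ang_max:
                continue
            cls = _classify(
                species[o_i], species[a_i],
                unit_id[o_i], unit_id[a_i], chain_id[o_i], chain_id[a_i],
            )
            out.append(HBond(int(o_i), int(h_i), a_i, float(d), float(dev), cls))
    return out


def _classify(sp_d, sp_a, u_d, u_a, c_d, c_a) -> str:
    pair = frozenset((sp_d, sp_a))
    if pair == {"cellulose"}:
        same_chain = (u_d == u_a) and (c_d == c_a)
        return "cellulose-cellulose intra" if same_chain else "cellulose-cellulose inter"
    if pair == {"callose"}:
        same_chain = (u_d == u_a) and (c_d == c_a)
        return "callose-callose intra" if same_chain else "callose-callose inter"
    if pair == {"cellulose", "callose"}:
        return "cellulose-callose"
    if pair == {"cellulose", "water"}:
        return "cellulose-water"
    if pair == {"callose", "water"}:
        return "callose-water"
    if pair == {"water"}:
        return "water-water"
    raise ValueError(f"unclassifiable species pair ({sp_d}, {sp_a})")


def tally_hbonds(hbonds: list[HBond], topology: Topology | None = None) -> dict[str, int]:
    """Counts per component-pair class; classes are exhaustive and disjoint."""
    counts = {cls: 0 for cls in HB_CLASSES}
    for hb in hbonds:
        if hb.hb_class not in counts:
            raise ValueError(f"unknown H-bond class {hb.hb_class!r}")
        counts[hb.hb_class] += 1
    return counts


def short_contacts(
    frame: Frame, topology: Topology, cutoff: float = 3.6
) -> pd.DataFrame:
    """Interunit heavy-atom contact pairs below the cutoff (minimum image).

    Only polysaccharide atoms participate, hydrogens are excluded, and both
    atoms must belong to *different* units -- chain-chain pairs inside one
    nanofiber are intrafiber and never counted.  Returns a DataFrame with
    columns i, j (frame atom indices), distance, unit_i/j, chain_i/j,
    ring_i/j.
    """
    topology.validate_against(frame)
    tab = topology.table
    mask = topology.polysaccharide_mask() & topology.heavy_mask()
    sel = np.flatnonzero(mask)
    cols = dict(
        i=[], j=[], distance=[], unit_i=[], unit_j=[],
        chain_i=[], chain_j=[], ring_i=[], ring_j=[],
    )
    if sel.size >= 2:
        box = frame.box
        pos = wrap_positions(frame.positions[sel], box)
        tree = cKDTree(pos, boxsize=box.lengths)
        pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
        if pairs.size:
            unit = tab["unit_id"].to_numpy()[sel]
            chain = tab["chain_id"].to_numpy()[sel]
            ring = tab["ring_index"].to_numpy()[sel]
            keep = unit[pairs[:, 0]] != unit[pairs[:, 1]]
            pairs = pairs[keep]
            a, b = pairs[:, 0], pairs[:, 1]
            d = np.linalg.norm(
                minimum_image_displacement(pos[a], pos[b], box), axis=-1
            )
            strict = d < cutoff
            a, b, d = a[strict], b[strict], d[strict]
            cols = dict(
                i=sel[a], j=sel[b], distance=d,
                unit_i=unit[a], unit_j=unit[b],
                chain_i=chain[a], chain_j=chain[b],
                ring_i=ring[a], ring_j=ring[b],
            )
    df = pd.DataFrame(cols)
    # canonical order: unit_i < unit_j
    if len(df):
        flip = df["unit_i"] > df["unit_j"]
        for x, y in (("i", "j"), ("unit_i", "unit_j"),
                     ("chain_i", "chain_j"), ("ring_i", "ring_j")):
            df.loc[flip, [x, y]] = df.loc[flip, [y, x]].to_numpy()
        df = df.sort_values(["unit_i", "unit_j", "i", "j"]).reset_index(drop=True)
    return df


def cluster_links(
    contacts: pd.DataFrame, topology: Topology, ring_window: int = 2
) -> list[Link]:
    """Merge contacts into links: localized clusters on one unit pair.

    Two contacts of the same unit pair belong to one link when their ring
    indices differ by at most ``ring_window`` on *both* sides (transitive
    closure).  The result is independent of the input contact order.
    """
    links: list[Link] = []
    if contacts.empty:
        return links
    kinds = topology.unit_kinds()
    for (ua, ub), grp in contacts.groupby(["unit_i", "unit_j"], sort=True):
        ra = grp["ring_i"].to_numpy()
        rb = grp["ring_j"].to_numpy()
        n = len(grp)
        close = (np.abs(ra[:, None] - ra[None, :]) <= ring_window) & (
            np.abs(rb[:, None] - rb[None, :]) <= ring_window
        )
        n_comp, labels = connected_components(coo_matrix(close), directed=False)
        for c in range(n_comp):
            sub = grp.iloc[np.flatnonzero(labels == c)]
            links.append(
                Link(
                    unit_a=int(ua), unit_b=int(ub),
                    kind_a=str(kinds[ua]), kind_b=str(kinds[ub]),
                    contacts=sub.reset_index(drop=True),
                    nc=len(sub),
                    ring_span_a=(int(sub["ring_i"].min()), int(sub["ring_i"].max())),
                    ring_span_b=(int(sub["ring_j"].min()), int(sub["ring_j"].max())),
                )
            )
    return links


def network_stats(links: list[Link], topology: Topology) -> dict:
    """Connectivity statistics of the unit graph.

    Returns average links per cellulose chain and per callose chain, the
    number of direct fiber-fiber links, the list of polysaccharide units
    without any link, and the number of connected components of the unit
    graph (isolated units count as their own components).
    """
    kinds = topology.unit_kinds()
    poly_units = kinds.index[kinds != "water"].to_numpy()
    kind_of = kinds.to_dict()

    g = nx.MultiGraph()
    g.add_nodes_from(poly_units)
    link_count: dict[int, int] = {int(u): 0 for u in poly_units}
    fiber_fiber = 0
    for lk in links:
        g.add_edge(lk.unit_a, lk.unit_b)
        link_count[lk.unit_a] = link_count.get(lk.unit_a, 0) + 1
        link_count[lk.unit_b] = link_count.get(lk.unit_b, 0) + 1
        if lk.kind_a == "nanofiber" and lk.kind_b == "nanofiber":
            fiber_fiber += 1

    def _avg(kind: str) -> float:
        ids = [int(u) for u in poly_units if kind_of[u] == kind]
        if not ids:
            return float("nan")
        return float(np.mean([link_count[u] for u in ids]))

    isolated = sorted(int(u) for u in poly_units if link_count[int(u)] == 0)
    return {
        "avg_links_per_cellulose_chain": _avg("cellulose_chain"),
        "avg_links_per_callose_chain": _avg("callose_chain"),
        "fiber_fiber_links": fiber_fiber,
        "isolated_units": isolated,
        "n_components": nx.number_connected_components(g),
        "links_per_unit": link_count,
        "n_links": len(links),
    }
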