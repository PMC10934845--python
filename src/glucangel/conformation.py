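"""Chain end-to-end statistics and water diffusion.

The end-to-end separation l of a chain is the distance between its first
and last pyranose-ring centroids after unwrapping.  The radial distribution
P(l) follows the normalization 4*pi * P(l) * l^2 * dl = dN(l), so that
4*pi * sum P(l) l^2 dl equals the chain count of the species.

Diffusion uses the Einstein relation: D = slope(MSD)/6 from a least-squares
fit over a window of lag times, with MSD averaged over particles and time
origins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Frame, Topology, unwrap_chain

__all__ = [
    "EndToEndDistribution",
    "DiffusionEstimate",
    "end_to_end",
    "radial_distribution",
    "msd",
    "diffusion_constant",
]


@dataclass
class EndToEndDistribution:
    species: str
    bin_centers: np.ndarray      # l, angstroms
    density: np.ndarray          # P(l)
    bin_width: float
    n_chains: int
    mean: float
    se: float

    def normalization(self) -> float:
        """4*pi * sum P(l) l^2 dl -- equals n_chains by construction."""
        return float(
            4.0 * np.pi * np.sum(self.density * self.bin_centers**2) * self.bin_width
        )


@dataclass
class DiffusionEstimate:
    lags: np.ndarray
    msd: np.ndarray
    fit_window: tuple[float, float]
    D: float
    se: float


def end_to_end(
    frame: Frame,
    topology: Topology,
    species: str,
    exclude_fiber_chains: bool = False,
) -> np.ndarray:
    """Per-chain end-to-end distances (A) for one species in one frame.

    Chains are unwrapped before measuring; l is the distance between the
    first and last ring centroids.  With ``exclude_fiber_chains`` the fully
    extended chains inside nanofibers are skipped, matching the convention
    used when quoting the single-chain average.  Refuses bundle samples
    whose chains are periodic (end-to-end undefined).
    """
    if topology.meta.get("periodic_chains"):
        raise ValueError(
            "end-to-end separation is undefined for periodically continued chains"
        )
    tab = topology.table
    kinds = topology.unit_kinds()
    values = []
    for unit_id, chain_id in topology.chains():
        sel = (tab["unit_id"] == unit_id) & (tab["chain_id"] == chain_id)
        sp = tab.loc[sel, "species"].iloc[0]
        if sp != species:
            continue
        if exclude_fiber_chains and kinds[unit_id] == "nanofiber":
            continue
        coords = unwrap_chain(frame, topology, unit_id, chain_id)
        sub = tab.loc[sel].reset_index(drop=True)
        rings = sub["ring_index"]
        ring_atoms_first = np.flatnonzero((rings == rings.min()) & _ring_mask(sub))
        ring_atoms_last = np.flatnonzero((rings == rings.max()) & _ring_mask(sub))
        c0 = coords[ring_atoms_first].mean(axis=0)
        c1 = coords[ring_atoms_last].mean(axis=0)
        values.append(float(np.linalg.norm(c1 - c0)))
    return np.asarray(values)


_RING_ATOM_NAMES = {"C1", "C2", "C3", "C4", "C5", "O5"}


def _ring_mask(sub) -> np.ndarray:
    return sub["name"].isin(_RING_ATOM_NAMES).to_numpy()


def radial_distribution(
    values: np.ndarray,
    bin_width: float = 5.0,
    species: str = "",
    l_max: float | None = None,
) -> EndToEndDistribution:
    """Histogram end-to-end distances into the radial density P(l)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no end-to-end values to histogram")
    if l_max is None:
        l_max = float(values.max()) + bin_width
    edges = np.arange(0.0, l_max + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = counts / (4.0 * np.pi * centers**2 * bin_width)
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return EndToEndDistribution(
        species=species, bin_centers=centers, density=density,
        bin_width=bin_width, n_chains=int(values.size), mean=mean, se=se,
    )


def msd(positions: np.ndarray, times: np.ndarray, max_lag: int | None = None
        ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-squared displacement over lag times.

    ``positions`` is an unwrapped (n_frames, n_particles, 3) array; the MSD
    at lag tau is averaged over all particles and all time origins.  Returns
    (lag_times, msd) with lag 0 included (MSD(0) = 0).
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 3 or positions.shape[0] < 2:
        raise ValueError("need an (n_frames >= 2, n_particles, 3) array")
    n_frames = positions.shape[0]
    times = np.asarray(times, dtype=float)
    if max_lag is None:
        max_lag = n_frames - 1
    max_lag = min(max_lag, n_frames - 1)
    out = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        disp = positions[lag:] - positions[:-lag]
        out[lag] = np.mean(np.sum(disp * disp, axis=-1))
    return times[: max_lag + 1] - times[0], out


def diffusion_constant(
    lags: np.ndarray,
    msd_values: np.ndarray,
    fit_window: tuple[float, float] = (0.2, 0.8),
) -> DiffusionEstimate:
    """Einstein-relation D from a linear fit of MSD(t) over a lag window.

    ``fit_window`` is given as fractions of the maximum lag; D = slope/6
    with the standard error propagated from the fit covariance.
    """
    lags = np.asarray(lags, dtype=float)
    msd_values = np.asarray(msd_values, dtype=float)
    lo, hi = fit_window
    t_max = lags.max()
    mask = (lags >= lo * t_max) & (lags <= hi * t_max)
    if mask.sum() < 2:
        raise ValueError("degenerate fit window: fewer than 2 points")
    x, y = lags[mask], msd_values[mask]
    if mask.sum() > 3:
        coeffs, cov = np.polyfit(x, y, 1, cov=True)
        se_slope = float(np.sqrt(cov[0, 0]))
    else:
        coeffs = np.polyfit(x, y, 1)
        se_slope = 0.0
    slope = coeffs[0]
    return DiffusionEstimate(
        lags=lags, msd=msd_values, fit_window=fit_window,
        D=float(slope / 6.0), se=se_slope / 6.0,
    )
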