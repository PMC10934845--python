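"""Partial structure factors on the reciprocal lattice of the periodic box.

S(k) = <|rho(k)|^2> / N with rho(k) = sum_i exp(-i k.R_i), evaluated on the
reciprocal lattice k = 2*pi*(nx/Lx, ny/Ly, nz/Lz) of the orthorhombic cell
(k = 0 excluded), averaged over frames and binned spherically.  Supported
particle selections are water oxygens and pyranose-ring centroids (the
unweighted center of the 5 ring carbons + ring oxygen, cellulose and
callose pooled).

Point particles only -- no atomic form factors.  Peak metrics use parabolic
interpolation for the position and linear interpolation of the half-height
crossings for the FWHM; the correlation length convention is xi = 2*pi/dk
and the real-space spacing d = 2*pi/k0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoxDims, Frame, Topology, minimum_image_displacement

__all__ = [
    "Spectrum",
    "PeakMetrics",
    "ring_centroids",
    "reciprocal_vectors",
    "density_fourier",
    "sk_vectors",
    "structure_factor",
    "peak_metrics",
    "correlation_length",
    "real_space_spacing",
]


@dataclass
class Spectrum:
    bin_centers: np.ndarray   # |k|, 1/A
    s_of_k: np.ndarray
    n_vectors: np.ndarray     # reciprocal vectors per bin
    selection: str = ""


@dataclass
class PeakMetrics:
    position: float        # k0, 1/A
    height: float
    fwhm: float            # dk, 1/A
    correlation_length: float  # xi = 2*pi/dk, A
    spacing: float             # d = 2*pi/k0, A


def correlation_length(fwhm: float) -> float:
    """xi = 2*pi / dk (angstroms for dk in 1/A)."""
    if fwhm <= 0:
        raise ValueError("FWHM must be positive")
    return 2.0 * np.pi / fwhm


def real_space_spacing(k0: float) -> float:
    """d = 2*pi / k0."""
    if k0 <= 0:
        raise ValueError("peak position must be positive")
    return 2.0 * np.pi / k0


def ring_centroids(frame: Frame, topology: Topology) -> np.ndarray:
    """One pseudo-particle per pyranose ring: centroid of its 5 C + 1 O
    ring atoms (minimum-image aware).  Cellulose and callose are pooled.
    """
    topology.validate_against(frame)
    tab = topology.table
    ring_names = {"C1", "C2", "C3", "C4", "C5", "O5"}
    mask = tab["name"].isin(ring_names) & tab["species"].isin(["cellulose", "callose"])
    sub = tab[mask]
    box = frame.box
    out = []
    for key, grp in sub.groupby(["unit_id", "chain_id", "ring_index"], sort=True):
        idx = grp.index.to_numpy()
        if len(idx) != 6:
            raise ValueError(
                f"ring {key} has {len(idx)} of 6 ring atoms; topology incomplete"
            )
        ref = frame.positions[idx[0]]
        offs = minimum_image_displacement(ref, frame.positions[idx], box)
        out.append(ref + offs.mean(axis=0))
    return np.asarray(out).reshape(-1, 3)


def reciprocal_vectors(
    box: BoxDims,
    k_max: float,
    max_per_shell: int = 2000,
    shell_width: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Reciprocal lattice vectors with 0 < |k| <= k_max (half space).

    Only one of each +/-k pair is returned (|rho(k)| is symmetric).  Shells
    (spherical bins of width ``shell_width``, default 2*pi/min(L)) holding
    more than ``max_per_shell`` vectors are uniformly subsampled, keeping
    exactness at low k and tractability at high k.
    """
    L = box.lengths
    dk = 2.0 * np.pi / L
    if k_max < dk.min():
        raise ValueError(
            f"k_max={k_max:.4g} below the first reciprocal shell {dk.min():.4g}"
        )
    nmax = np.ceil(k_max / dk).astype(int)
    nx = np.arange(0, nmax[0] + 1)
    ny = np.arange(-nmax[1], nmax[1] + 1)
    nz = np.arange(-nmax[2], nmax[2] + 1)
    grid = np.stack(np.meshgrid(nx, ny, nz, indexing="ij"), axis=-1).reshape(-1, 3)
    # half space: nx > 0, or nx == 0 and (ny > 0 or (ny == 0 and nz > 0))
    keep = (grid[:, 0] > 0) | (
        (grid[:, 0] == 0)
        & ((grid[:, 1] > 0) | ((grid[:, 1] == 0) & (grid[:, 2] > 0)))
    )
    grid = grid[keep]
    k = grid * dk
    kmag = np.linalg.norm(k, axis=1)
    sel = kmag <= k_max
    k, kmag = k[sel], kmag[sel]

    if shell_width is None:
        shell_width = dk.min()
    shell = np.floor(kmag / shell_width).astype(int)
    if rng is None:
        rng = np.random.default_rng(0)
    keep_idx = []
    for s in np.unique(shell):
        idx = np.flatnonzero(shell == s)
        if idx.size > max_per_shell:
            idx = rng.choice(idx, size=max_per_shell, replace=False)
        keep_idx.append(idx)
    keep_idx = np.sort(np.concatenate(keep_idx))
    return k[keep_idx]


def density_fourier(
    positions: np.ndarray, kvecs: np.ndarray, chunk: int = 1024
) -> np.ndarray:
    """rho(k) = sum_i exp(-i k.R_i) for each reciprocal vector.

    rho(-k) is the complex conjugate of rho(k) and rho(0) = N.  The k-vector
    list is processed in chunks to bound the N x M phase matrix in memory.
    """
    positions = np.asarray(positions, float)
    kvecs = np.asarray(kvecs, float)
    out = np.empty(len(kvecs), dtype=complex)
    for s in range(0, len(kvecs), chunk):
        phases = positions @ kvecs[s: s + chunk].T
        out[s: s + chunk] = np.exp(-1j * phases).sum(axis=0)
    return out


def sk_vectors(
    frames: list[np.ndarray] | np.ndarray,
    box: BoxDims,
    kvecs: np.ndarray,
) -> np.ndarray:
    """Frame-averaged S(k) = <|rho(k)|^2>/N per reciprocal vector (unbinned).

    Useful for Bragg conditions, where spherical binning would dilute a
    single resonant vector among the non-resonant ones in its shell.
    """
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        frames = [frames]
    acc = np.zeros(len(kvecs))
    for pos in frames:
        rho = density_fourier(pos, kvecs)
        acc += (rho.real**2 + rho.imag**2) / len(pos)
    return acc / len(frames)


def structure_factor(
    frames: list[np.ndarray] | np.ndarray,
    box: BoxDims,
    k_max: float,
    bin_width: float | None = None,
    max_per_shell: int = 2000,
    selection: str = "",
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """S(k) = <|rho(k)|^2>/N, frame-averaged, spherically binned.

    ``frames`` is a list of (N, 3) position arrays (one per frame) of the
    selected particles; N may vary per frame only in pathological cases and
    is taken per frame.  Default bin width is one reciprocal shell,
    2*pi/min(L).
    """
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        frames = [frames]
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    kvecs = reciprocal_vectors(box, k_max, max_per_shell=max_per_shell, rng=rng)
    kmag = np.linalg.norm(kvecs, axis=1)
    if bin_width is None:
        bin_width = 2.0 * np.pi / box.lengths.min()

    acc = np.zeros(len(kvecs))
    for pos in frames:
        pos = np.asarray(pos, dtype=float)
        n = pos.shape[0]
        if n == 0:
            raise ValueError("empty selection in a frame")
        rho = density_fourier(pos, kvecs)
        acc += (rho.real**2 + rho.imag**2) / n
    acc /= len(frames)

    nbins = int(np.ceil(k_max / bin_width))
    edges = np.arange(nbins + 1) * bin_width
    which = np.clip(np.digitize(kmag, edges) - 1, 0, nbins - 1)
    s_of_k = np.zeros(nbins)
    counts = np.zeros(nbins, dtype=int)
    np.add.at(s_of_k, which, acc)
    np.add.at(counts, which, 1)
    occupied = counts > 0
    s_of_k[occupied] /= counts[occupied]
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Spectrum(
        bin_centers=centers[occupied],
        s_of_k=s_of_k[occupied],
        n_vectors=counts[occupied],
        selection=selection,
    )


def peak_metrics(
    spectrum: Spectrum,
    k_range: tuple[float, float] | None = None,
    background: float = 0.0,
) -> PeakMetrics:
    """Locate a peak and report position, FWHM, correlation length, spacing.

    The peak position is refined by parabolic interpolation over the three
    bins around the maximum; the FWHM is measured at half of the
    background-subtracted height by linear interpolation of the crossings.
    Raises when the restricted spectrum is monotone (no interior maximum).
    """
    k = spectrum.bin_centers
    s = spectrum.s_of_k - background
    if k_range is not None:
        m = (k >= k_range[0]) & (k <= k_range[1])
        k, s = k[m], s[m]
    if k.size < 3:
        raise ValueError("no peak: fewer than 3 bins in range")
    i = int(np.argmax(s))
    if i == 0 or i == k.size - 1:
        raise ValueError("no peak: maximum at range boundary (monotone spectrum?)")

    # parabolic refinement
    y0, y1, y2 = s[i - 1], s[i], s[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom != 0.0:
        delta = 0.5 * (y0 - y2) / denom
        k0 = k[i] + delta * (k[i + 1] - k[i])
        height = y1 - 0.25 * (y0 - y2) * delta
    else:
        k0, height = float(k[i]), float(y1)

    half = height / 2.0
    left = _crossing(k[: i + 1], s[: i + 1], half, rising=True)
    right = _crossing(k[i:], s[i:], half, rising=False)
    fwhm = right - left
    return PeakMetrics(
        position=float(k0),
        height=float(height),
        fwhm=float(fwhm),
        correlation_length=correlation_length(fwhm),
        spacing=real_space_spacing(float(k0)),
    )


def _crossing(k: np.ndarray, s: np.ndarray, level: float, rising: bool) -> float:
    """Linear-interpolated k where s crosses ``level`` adjacent to the peak."""
    if rising:
        below = np.flatnonzero(s[:-1] < level)
        if below.size == 0:
            # peak extends to the spectrum edge (e.g. k -> 0 peak): clamp
            return float(k[0])
        j = below[-1]
    else:
        below = np.flatnonzero(s[1:] < level)
        if below.size == 0:
            return float(k[-1])
        j = below[0]
    k1, k2 = k[j], k[j + 1]
    s1, s2 = s[j], s[j + 1]
    if s2 == s1:
        return float(k1)
    return float(k1 + (level - s1) * (k2 - k1) / (s2 - s1))
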