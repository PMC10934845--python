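"""Elastic moduli from equilibrium fluctuations and finite deformation.

Three routes are implemented:

* **Bulk modulus** from constant-pressure volume fluctuations,
  B = k_B T <V> / Var(V); the isothermal compressibility is K_T = 1/B.

* **C11, C12 and Young's modulus** from the fluctuations of the three
  diagonal strain components of an orthorhombic box around a cubic
  reference: the compliance covariances k_B T S_ij / V0 = <eps_i eps_j>
  give S11 and S12 (symmetry-averaged over the equivalent index pairs
  (xx,xx)=(yy,yy)=(zz,zz) and (xx,yy)=(xx,zz)=(yy,zz)), which invert to
  C11 = (S11+S12)/[(S11-S12)(S11+2S12)], C12 = -S12/[(S11-S12)(S11+2S12)],
  and Y = (C11-C12)(C11+2C12)/(C11+C12) = 1/S11.

* **Finite deformation**: a Pade [1/1] fit to the measured strain
  <dL>/L0 versus applied uniaxial stress sigma, differentiated
  analytically, gives the stress-dependent Young's modulus
  Y(sigma) = 1 / f'(sigma).

Standard errors come from block averaging (10 blocks by default).
Temperature defaults to 300 K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import A3_PER_M3, KB_J_PER_K, PA_PER_GPA, PA_PER_MPA

__all__ = [
    "VolumeSeries",
    "StrainSeries",
    "ElasticConstants",
    "StressStrainCurve",
    "bulk_modulus",
    "strain_series",
    "elastic_constants",
    "elastic_constants_from_compliances",
    "pade_young",
    "young_from_constants",
]


@dataclass
class VolumeSeries:
    """Box volume time series: time (ps), V (A^3), temperature (K)."""

    time: np.ndarray
    volume: np.ndarray
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.volume.size < 2:
            raise ValueError("volume series needs at least 2 samples")
        if np.any(self.volume <= 0):
            raise ValueError("volumes must be positive")


@dataclass
class StrainSeries:
    """Diagonal strain triples (eps_xx, eps_yy, eps_zz) per frame."""

    time: np.ndarray
    strains: np.ndarray          # (n, 3)
    reference_sides: np.ndarray  # <Lx>, <Ly>, <Lz>, angstroms
    temperature: float = 300.0

    def __post_init__(self) -> None:
        self.strains = np.asarray(self.strains, dtype=float)
        if self.strains.ndim != 2 or self.strains.shape[1] != 3:
            raise ValueError("strains must have shape (n, 3)")

    @property
    def v0(self) -> float:
        """Reference volume <Lx><Ly><Lz>, A^3."""
        return float(np.prod(self.reference_sides))


@dataclass
class BulkEstimate:
    B: float          # GPa
    se: float         # GPa
    mean_volume: float
    drift_flagged: bool = False


@dataclass
class ElasticConstants:
    C11: float        # GPa
    C12: float        # GPa
    Y: float          # MPa
    B: float          # GPa, (C11 + 2 C12)/3
    se_C11: float = 0.0
    se_C12: float = 0.0
    se_Y: float = 0.0
    S11: float = 0.0  # 1/GPa
    S12: float = 0.0


@dataclass
class StressStrainCurve:
    stress: np.ndarray           # MPa
    strain: np.ndarray           # <dL>/L0
    strain_se: np.ndarray | None
    a: float                     # Pade f(s) = a*s / (1 + c*s)
    c: float
    breakdown: bool              # pole of the fit inside the data range
    young: dict = field(default_factory=dict)   # sigma -> Y(sigma), MPa

    def young_at(self, sigma: float) -> float:
        """Y(sigma) = 1/f'(sigma) = (1 + c*sigma)^2 / a, MPa."""
        return (1.0 + self.c * sigma) ** 2 / self.a


def _block_se(values: np.ndarray, estimator, n_blocks: int = 10) -> float:
    """Standard error of an estimator by block averaging."""
    n = len(values)
    if n < n_blocks:
        return float("nan")
    size = n // n_blocks
    blocks = [estimator(values[i * size:(i + 1) * size]) for i in range(n_blocks)]
    return float(np.std(blocks, ddof=1) / np.sqrt(n_blocks))


def bulk_modulus(
    series: VolumeSeries, n_blocks: int = 10, drift_tol: float = 0.5
) -> BulkEstimate:
    """B = k_B T <V> / Var(V), in GPa, with block-averaged standard error.

    A monotone drift (first-half/second-half mean difference beyond
    ``drift_tol`` standard deviations) triggers a warning and flags the
    estimate; zero variance is an error.
    """
    v = series.volume
    var = v.var(ddof=1)
    if var == 0.0:
        raise ValueError("zero volume variance: bulk modulus undefined")
    drift = False
    half = len(v) // 2
    if abs(v[:half].mean() - v[half:].mean()) > drift_tol * v.std(ddof=1):
        warnings.warn("volume series drifts; bulk modulus estimate flagged")
        drift = True

    def estimate(vals: np.ndarray) -> float:
        v_m3 = vals / A3_PER_M3
        return (
            KB_J_PER_K * series.temperature * v_m3.mean() / v_m3.var(ddof=1)
        ) / PA_PER_GPA

    return BulkEstimate(
        B=estimate(v),
        se=_block_se(v, estimate, n_blocks),
        mean_volume=float(v.mean()),
        drift_flagged=drift,
    )


def strain_series(
    time: np.ndarray, sides: np.ndarray, temperature: float = 300.0
) -> StrainSeries:
    """Diagonal strains eps_ii = (L_i - <L_i>) / <L_i> from box-side series.

    ``sides`` has shape (n, 3) in angstroms.
    """
    sides = np.asarray(sides, dtype=float)
    if sides.ndim != 2 or sides.shape[1] != 3 or sides.shape[0] < 2:
        raise ValueError("sides must have shape (n >= 2, 3)")
    if np.any(sides <= 0):
        raise ValueError("box sides must be positive")
    ref = sides.mean(axis=0)
    eps = (sides - ref) / ref
    return StrainSeries(np.asarray(time, float), eps, ref, temperature)


def elastic_constants(strains: StrainSeries, n_blocks: int = 10) -> ElasticConstants:
    """C11, C12 (GPa) and Y (MPa) from diagonal-strain fluctuations.

    Compliances come from the symmetry-averaged covariances
    S11 = V0 <eps_xx^2> / (k_B T), S12 = V0 <eps_xx eps_yy> / (k_B T);
    inversion of the cubic compliance matrix yields C11 and C12, and Y
    follows as (C11-C12)(C11+2C12)/(C11+C12) (identically 1/S11).
    """
    eps = strains.strains
    kbt = KB_J_PER_K * strains.temperature
    v0_m3 = strains.v0 / A3_PER_M3
    pref = v0_m3 / kbt  # 1/Pa per unit strain covariance

    def constants(e: np.ndarray) -> tuple[float, float, float]:
        s11 = pref * np.mean(
            [np.mean(e[:, i] * e[:, i]) for i in range(3)]
        )
        s12 = pref * np.mean(
            [np.mean(e[:, i] * e[:, j]) for i, j in ((0, 1), (0, 2), (1, 2))]
        )
        return _invert_compliances(s11, s12)

    c11, c12, y = constants(eps)

    ses = [float("nan")] * 3
    if len(eps) >= n_blocks:
        size = len(eps) // n_blocks
        blocks = np.array(
            [constants(eps[i * size:(i + 1) * size]) for i in range(n_blocks)]
        )
        ses = list(blocks.std(axis=0, ddof=1) / np.sqrt(n_blocks))

    # recompute compliances for the report (GPa^-1)
    s11 = pref * np.mean([np.mean(eps[:, i] ** 2) for i in range(3)]) * PA_PER_GPA
    s12 = pref * np.mean(
        [np.mean(eps[:, i] * eps[:, j]) for i, j in ((0, 1), (0, 2), (1, 2))]
    ) * PA_PER_GPA
    return ElasticConstants(
        C11=c11 / PA_PER_GPA,
        C12=c12 / PA_PER_GPA,
        Y=y / PA_PER_MPA,
        B=(c11 + 2.0 * c12) / 3.0 / PA_PER_GPA,
        se_C11=ses[0] / PA_PER_GPA,
        se_C12=ses[1] / PA_PER_GPA,
        se_Y=ses[2] / PA_PER_MPA,
        S11=s11,
        S12=s12,
    )


def _invert_compliances(s11: float, s12: float) -> tuple[float, float, float]:
    """(C11, C12, Y) in Pa from compliances in 1/Pa."""
    denom = (s11 - s12) * (s11 + 2.0 * s12)
    if denom == 0.0 or s11 == s12:
        raise ValueError("vanishing shear response: S11 == S12 (singular compliance)")
    c11 = (s11 + s12) / denom
    c12 = -s12 / denom
    y = young_from_constants(c11, c12)
    return c11, c12, y


def elastic_constants_from_compliances(
    s11_gpa_inv: float, s12_gpa_inv: float
) -> ElasticConstants:
    """Invert noiseless compliances (1/GPa) directly; Y = 1/S11 exactly."""
    c11, c12, y = _invert_compliances(
        s11_gpa_inv / PA_PER_GPA, s12_gpa_inv / PA_PER_GPA
    )
    return ElasticConstants(
        C11=c11 / PA_PER_GPA, C12=c12 / PA_PER_GPA, Y=y / PA_PER_MPA,
        B=(c11 + 2 * c12) / 3.0 / PA_PER_GPA,
        S11=s11_gpa_inv, S12=s12_gpa_inv,
    )


def young_from_constants(c11: float, c12: float) -> float:
    """Y = (C11 - C12)(C11 + 2 C12)/(C11 + C12), any consistent units."""
    if c11 + c12 == 0.0:
        raise ValueError("C11 + C12 = 0: Young's modulus undefined")
    return (c11 - c12) * (c11 + 2.0 * c12) / (c11 + c12)


def pade_young(
    stress: np.ndarray,
    strain: np.ndarray,
    strain_se: np.ndarray | None = None,
    eval_at: tuple[float, ...] = (),
) -> StressStrainCurve:
    """Fit f(sigma) = a*sigma/(1 + c*sigma) and differentiate analytically.

    ``stress`` in MPa, ``strain`` dimensionless <dL>/L0; weighted least
    squares when standard errors are given.  Y(sigma) = 1/f'(sigma) =
    (1 + c*sigma)^2/a in MPa.  A pole of the fitted Pade inside the data
    range is flagged as mechanical breakdown of the description.
    """
    stress = np.asarray(stress, dtype=float)
    strain = np.asarray(strain, dtype=float)
    if stress.size < 4:
        raise ValueError("need at least 4 stress-strain points for a Pade [1/1] fit")
    if strain_se is not None:
        strain_se = np.asarray(strain_se, dtype=float)
        if not np.all(strain_se > 0):
            strain_se = None  # degenerate weights: fall back to unweighted

    def f(s, a, c):
        return a * s / (1.0 + c * s)

    slope0 = strain[-1] / stress[-1] if stress[-1] != 0 else 1.0
    try:
        popt, _pcov = curve_fit(
            f, stress, strain, p0=[slope0, 0.0],
            sigma=strain_se, absolute_sigma=strain_se is not None,
            maxfev=10000,
        )
    except RuntimeError as exc:
        resid = np.nan
        raise RuntimeError(f"Pade fit failed to converge: {exc}; residual={resid}")
    a, c = float(popt[0]), float(popt[1])
    if a <= 0:
        raise RuntimeError(f"Pade fit nonphysical: a = {a:.3g} <= 0")
    # a least-squares Pade cannot place its pole strictly inside positive
    # data, so "divergence within the sampled range" manifests as a pole at
    # or just beyond the largest stress; flag within a 20 % margin
    breakdown = False
    if c < 0:
        pole = -1.0 / c
        breakdown = bool(pole <= 1.2 * stress.max())
    curve = StressStrainCurve(
        stress=stress, strain=strain, strain_se=strain_se,
        a=a, c=c, breakdown=breakdown,
    )
    curve.young = {float(s): curve.young_at(float(s)) for s in eval_at}
    return curve
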