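"""Samplers, moment formulas and z-standardization for the simulation families.

This module is the synthetic-data stage of the package.  It emulates the kind
of data a quantitative-EEG normative database holds: nominally Gaussian scores
that are in fact mildly to strongly fat-tailed.  The primary family is the
lognormal ``exp(sigma * Z)`` with ``Z`` standard normal and the log-mean fixed
at 0 — z-standardization makes the log-mean irrelevant, and fixing it keeps
every closed-form oracle below a one-liner.  Alternate fat-tailed families
(Student t, chi-squared, Pareto) are provided for the supplementary
false-positive comparisons.

Moment conventions
------------------
Sample skewness ``g1 = m3 / m2**1.5`` and kurtosis ``b2 = m4 / m2**2`` use
central moments with the ``1/n`` denominator and no small-sample correction,
so a Gaussian sample has kurtosis near 3 and the "kurtosis ratio" ``b2 / 3``
is near 1.  This matches the convention of the R ``moments`` package commonly
used to report normative-database moments.  Standardization, by contrast,
uses the conventional ``n - 1`` sample SD; at the simulated sample sizes the
difference is far below every tolerance in the package but is fixed for
bit-reproducibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import DegenerateSampleError, ParameterError

__all__ = [
    "TABLE1_SIGMAS",
    "STUDENT_T_DFS",
    "CHI_SQUARED_DFS",
    "PARETO_SHAPES",
    "RELIABILITY_GRID",
    "DistributionSpec",
    "StandardizedSample",
    "MomentSummary",
    "LognormalMoments",
    "PairedSample",
    "sample",
    "standardize",
    "standardize_rows",
    "sample_matrix",
    "sample_moments",
    "row_moments",
    "lognormal_theoretical_moments",
    "theoretical_kurtosis_ratio",
    "correlated_pairs",
    "paired_matrices",
]

#: Log-scale standard deviations of the lognormal study grid.  They span
#: kurtosis ratios from 1.00 (indistinguishable from Gaussian) to ~2.55.
TABLE1_SIGMAS: tuple[float, ...] = (
    0.001, 0.100, 0.157, 0.214, 0.271, 0.329, 0.386, 0.443, 0.500,
)

#: Degrees of freedom for the supplementary Student-t comparisons.
STUDENT_T_DFS: tuple[float, ...] = (3, 5, 8, 12, 16, 20, 30, 40)

#: Degrees of freedom for the supplementary chi-squared comparisons.
CHI_SQUARED_DFS: tuple[float, ...] = (1, 2, 3, 5, 8, 12, 16, 20)

#: Tail exponents for the supplementary Pareto comparisons (location fixed 1).
PARETO_SHAPES: tuple[float, ...] = (0.5, 1, 1.5, 2, 2.5, 3, 5, 8)

#: Test-retest reliabilities used in the pre/post simulation: poor,
#: acceptable, good, excellent.
RELIABILITY_GRID: tuple[float, ...] = (0.5, 0.7, 0.8, 0.95)

_FAMILIES = ("gaussian", "lognormal", "student_t", "chi_squared", "pareto")


@dataclass(frozen=True)
class DistributionSpec:
    """A generating family together with exactly its relevant parameters.

    Parameters irrelevant to ``family`` must be left ``None``; the constructor
    enforces this so a spec is always unambiguous about what it generates.
    Prefer the classmethod constructors (:meth:`lognormal`, :meth:`gaussian`,
    ...) over positional construction.
    """

    family: str
    sigma_log: float | None = None
    df: float | None = None
    shape: float | None = None
    location: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterError(
                f"unknown family {self.family!r}; expected one of {_FAMILIES}"
            )
        required = {
            "gaussian": (),
            "lognormal": ("sigma_log",),
            "student_t": ("df",),
            "chi_squared": ("df",),
            "pareto": ("shape", "location"),
        }[self.family]
        for name in ("sigma_log", "df", "shape", "location"):
            value = getattr(self, name)
            if name in required:
                if value is None:
                    raise ParameterError(
                        f"family {self.family!r} requires parameter {name!r}"
                    )
                if not math.isfinite(value) or value <= 0:
                    raise ParameterError(
                        f"{name} must be a positive finite real, got {value!r}"
                    )
            elif value is not None:
                raise ParameterError(
                    f"parameter {name!r} is not meaningful for family "
                    f"{self.family!r}"
                )

    @classmethod
    def gaussian(cls) -> "DistributionSpec":
        return cls("gaussian")

    @classmethod
    def lognormal(cls, sigma_log: float) -> "DistributionSpec":
        return cls("lognormal", sigma_log=float(sigma_log))

    @classmethod
    def student_t(cls, df: float) -> "DistributionSpec":
        return cls("student_t", df=float(df))

    @classmethod
    def chi_squared(cls, df: float) -> "DistributionSpec":
        return cls("chi_squared", df=float(df))

    @classmethod
    def pareto(cls, shape: float, location: float = 1.0) -> "DistributionSpec":
        return cls("pareto", shape=float(shape), location=float(location))

    @property
    def param(self) -> float | None:
        """The single scalar that indexes this family's fat-tailedness."""
        return {
            "gaussian": None,
            "lognormal": self.sigma_log,
            "student_t": self.df,
            "chi_squared": self.df,
            "pareto": self.shape,
        }[self.family]

    @property
    def label(self) -> str:
        if self.family == "gaussian":
            return "gaussian"
        return f"{self.family}({self.param:g})"


@dataclass(frozen=True, eq=False)
class StandardizedSample:
    """One z-standardized replicate with its provenance.

    ``values`` has sample mean 0 and sample SD 1 (``n - 1`` denominator)
    within 1e-10; this is checked at construction.
    """

    values: np.ndarray
    n: int
    spec: DistributionSpec | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or len(values) != self.n:
            raise ParameterError("values must be a 1-d vector of length n")
        if abs(values.mean()) > 1e-10 or abs(values.std(ddof=1) - 1.0) > 1e-10:
            raise DegenerateSampleError(
                "values are not z-standardized to mean 0 / SD 1"
            )


class MomentSummary(NamedTuple):
    """Sample skewness/kurtosis in the normative-database convention."""

    skewness_g1: float
    kurtosis_b2: float
    kurtosis_ratio: float  # b2 / 3, the ratio to the Gaussian kurtosis


class LognormalMoments(NamedTuple):
    """Exact raw-scale moments of ``exp(sigma * Z)``."""

    mean: float
    sd: float
    skewness: float
    excess_kurtosis: float


@dataclass(frozen=True, eq=False)
class PairedSample:
    """Pre/post score vectors generated at test-retest reliability ``rho_jj``.

    Both margins are z-standardized; ``diff`` is ``pre - post`` elementwise,
    the quantity compared against the critical difference.
    """

    pre: np.ndarray
    post: np.ndarray
    diff: np.ndarray
    rho_jj: float
    spec: DistributionSpec
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("pre", "post", "diff"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if not (len(self.pre) == len(self.post) == len(self.diff)):
            raise ParameterError("pre, post and diff must have equal length")
        if not np.allclose(self.diff, self.pre - self.post, atol=1e-12):
            raise ParameterError("diff must equal pre - post elementwise")

    @property
    def n(self) -> int:
        return len(self.pre)


def sample_matrix(
    spec: DistributionSpec, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Draw an array of independent raw-scale values from ``spec``.

    This is the low-level sampler the simulation modules use to draw whole
    replicate blocks at once; :func:`sample` wraps it for single vectors.
    """
    if spec.family == "gaussian":
        return rng.standard_normal(shape)
    if spec.family == "lognormal":
        return np.exp(spec.sigma_log * rng.standard_normal(shape))
    if spec.family == "student_t":
        return rng.standard_t(spec.df, shape)
    if spec.family == "chi_squared":
        return rng.chisquare(spec.df, shape)
    # Pareto I with minimum `location`: numpy's pareto() is the Lomax form.
    return spec.location * (1.0 + rng.pareto(spec.shape, shape))


def sample(spec: DistributionSpec, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` independent raw-scale values; bit-reproducible in ``seed``."""
    if n < 2:
        raise ParameterError(f"need n >= 2 draws, got {n}")
    rng = np.random.default_rng(seed)
    return sample_matrix(spec, (n,), rng)


def standardize(
    values: np.ndarray | StandardizedSample,
    spec: DistributionSpec | None = None,
    seed: int | None = None,
) -> StandardizedSample:
    """Z-standardize a vector to mean 0, SD 1 (``n - 1`` denominator).

    Idempotent and affine-equivariant: ``standardize(a * x + b)`` equals
    ``standardize(x)`` for any ``a > 0``.
    """
    if isinstance(values, StandardizedSample):
        spec = spec or values.spec
        seed = seed if seed is not None else values.seed
        values = values.values
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ParameterError("standardize expects a 1-d vector of length >= 2")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateSampleError("cannot standardize a constant sample")
    z = (x - x.mean()) / sd
    # One exact re-centering pass keeps the mean-0 invariant at the 1e-10
    # level even for badly scaled inputs.
    z = (z - z.mean()) / z.std(ddof=1)
    return StandardizedSample(values=z, n=len(z), spec=spec, seed=seed)


def standardize_rows(matrix: np.ndarray) -> np.ndarray:
    """Row-wise z-standardization of a (replicates, n) block."""
    x = np.asarray(matrix, dtype=float)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0) or not np.all(np.isfinite(sd)):
        raise DegenerateSampleError("a replicate row is constant")
    return (x - x.mean(axis=1, keepdims=True)) / sd


def sample_moments(values: np.ndarray | StandardizedSample) -> MomentSummary:
    """Sample skewness g1 and kurtosis b2 (1/n central moments)."""
    if isinstance(values, StandardizedSample):
        values = values.values
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ParameterError("sample_moments expects a 1-d vector with n >= 4")
    xc = x - x.mean()
    m2 = np.mean(xc**2)
    if m2 == 0:
        raise DegenerateSampleError("sample_moments is undefined for constant data")
    g1 = np.mean(xc**3) / m2**1.5
    b2 = np.mean(xc**4) / m2**2
    return MomentSummary(float(g1), float(b2), float(b2) / 3.0)


def row_moments(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (g1, b2) per row of a (replicates, n) block."""
    x = np.asarray(matrix, dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    m2 = np.mean(xc**2, axis=1)
    if np.any(m2 == 0):
        raise DegenerateSampleError("a replicate row is constant")
    g1 = np.mean(xc**3, axis=1) / m2**1.5
    b2 = np.mean(xc**4, axis=1) / m2**2
    return g1, b2


def lognormal_theoretical_moments(sigma_log: float) -> LognormalMoments:
    """Exact moments of the lognormal ``exp(sigma * Z)``.

    mean = e^{s^2/2}, var = (e^{s^2}-1) e^{s^2},
    skew = (e^{s^2}+2) sqrt(e^{s^2}-1),
    excess kurtosis = e^{4 s^2} + 2 e^{3 s^2} + 3 e^{2 s^2} - 6.
    """
    if not (sigma_log > 0 and math.isfinite(sigma_log)):
        raise ParameterError(f"sigma_log must be > 0, got {sigma_log!r}")
    s2 = sigma_log**2
    es = math.exp(s2)
    mean = math.exp(s2 / 2.0)
    var = (es - 1.0) * es
    skew = (es + 2.0) * math.sqrt(es - 1.0)
    excess = math.exp(4 * s2) + 2 * math.exp(3 * s2) + 3 * math.exp(2 * s2) - 6.0
    return LognormalMoments(mean, math.sqrt(var), skew, excess)


def theoretical_kurtosis_ratio(spec: DistributionSpec) -> float:
    """Population kurtosis divided by the Gaussian's 3; ``inf`` if undefined.

    Families whose fourth moment does not exist (t with df <= 4, Pareto with
    shape <= 4) return ``inf`` rather than raising: non-existence is a
    legitimate value on the fat-tailedness axis, not an input error.
    """
    if spec.family == "gaussian":
        return 1.0
    if spec.family == "lognormal":
        excess = lognormal_theoretical_moments(spec.sigma_log).excess_kurtosis
    elif spec.family == "student_t":
        if spec.df <= 4:
            return math.inf
        excess = 6.0 / (spec.df - 4.0)
    elif spec.family == "chi_squared":
        excess = 12.0 / spec.df
    else:  # pareto
        a = spec.shape
        if a <= 4:
            return math.inf
        excess = 6.0 * (a**3 + a**2 - 6.0 * a - 2.0) / (a * (a - 3.0) * (a - 4.0))
    return (3.0 + excess) / 3.0


def _latent_rho(spec: DistributionSpec, rho: float, corr_scale: str) -> float:
    """Latent-scale correlation that realises the requested pairing scheme."""
    if corr_scale not in ("latent", "raw"):
        raise ParameterError(f"corr_scale must be 'latent' or 'raw', got {corr_scale!r}")
    if corr_scale == "latent" or spec.family == "gaussian":
        return rho
    # Raw-scale target for the lognormal: invert the bivariate-lognormal
    # correlation (e^{rho_l s^2} - 1) / (e^{s^2} - 1) = rho.
    s2 = spec.sigma_log**2
    arg = 1.0 + rho * (math.exp(s2) - 1.0)
    if arg <= 0:
        raise ParameterError(
            f"raw-scale correlation {rho} is unattainable for sigma_log "
            f"{spec.sigma_log}"
        )
    return math.log(arg) / s2


def paired_matrices(
    spec: DistributionSpec,
    rho: float,
    k: int,
    n: int,
    rng: np.random.Generator,
    corr_scale: str = "latent",
) -> tuple[np.ndarray, np.ndarray]:
    """(k, n) pre and post blocks, each row-standardized, correlated at rho.

    The pair is built from a bivariate standard normal on the latent scale;
    for the lognormal family each margin is passed through ``exp(sigma *)``
    before standardization.  With ``corr_scale='raw'`` the latent correlation
    is adjusted so the raw-scale (pre-transform) correlation equals ``rho``.
    """
    if abs(rho) > 1:
        raise ParameterError(f"|rho| must be <= 1, got {rho}")
    if spec.family not in ("gaussian", "lognormal"):
        raise ParameterError(
            "paired generation is defined for the gaussian and lognormal "
            f"families, not {spec.family!r}"
        )
    r = _latent_rho(spec, rho, corr_scale)
    z1 = rng.standard_normal((k, n))
    z2 = rng.standard_normal((k, n))
    zb = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * z2
    if spec.family == "lognormal":
        pre_raw = np.exp(spec.sigma_log * z1)
        post_raw = np.exp(spec.sigma_log * zb)
    else:
        pre_raw, post_raw = z1, zb
    return standardize_rows(pre_raw), standardize_rows(post_raw)


def correlated_pairs(
    spec: DistributionSpec,
    rho: float,
    n: int,
    seed: int,
    corr_scale: str = "latent",
) -> PairedSample:
    """One pre/post replicate of size ``n`` at test-retest reliability rho."""
    if n < 3:
        raise ParameterError(f"need n >= 3 pairs, got {n}")
    rng = np.random.default_rng(seed)
    pre, post = paired_matrices(spec, rho, 1, n, rng, corr_scale)
    pre, post = pre[0], post[0]
    return PairedSample(
        pre=pre, post=post, diff=pre - post, rho_jj=rho, spec=spec, seed=seed
    )
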