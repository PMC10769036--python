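"""Diagnostics and packaging: QQ data, density curves, percentile cut-offs,
the moments table, and CSV/JSON output with reproducibility sidecars.

Figures themselves are out of scope; every operation emits plot-ready
tables.  Tabular outputs are CSV with a header row; each CLI run writes a
JSON sidecar holding the fully resolved configuration, the seed and the
package version, from which the run can be reproduced bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import distributions as dist
from .distributions import DistributionSpec, StandardizedSample
from .exceptions import ParameterError, PrecisionError

__all__ = [
    "QQData",
    "PercentileCutoff",
    "qq_data",
    "density_comparison",
    "standardized_lognormal_density",
    "percentile_cutoff",
    "moments_table",
    "write_table",
    "read_sidecar",
]


@dataclass(frozen=True, eq=False)
class QQData:
    """Paired quantiles for a normal QQ plot at plotting positions (i-0.5)/n."""

    theoretical_quantiles: np.ndarray
    sample_quantiles: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theoretical": self.theoretical_quantiles,
                "sample": self.sample_quantiles,
            }
        )


@dataclass(frozen=True)
class PercentileCutoff:
    """Empirical percentile cut-off with a bootstrap percentile CI."""

    level: float
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int


def qq_data(sample: StandardizedSample | np.ndarray) -> QQData:
    """Sorted sample quantiles against standard-normal quantiles.

    Fat tails show up as curvature: upper-tail sample quantiles above the
    Gaussian line.
    """
    values = sample.values if isinstance(sample, StandardizedSample) else np.asarray(sample, float)
    n = len(values)
    if n < 10:
        raise ParameterError(f"need n >= 10 for a QQ plot, got {n}")
    positions = (np.arange(1, n + 1) - 0.5) / n
    return QQData(
        theoretical_quantiles=norm.ppf(positions),
        sample_quantiles=np.sort(values),
        n=n,
    )


def standardized_lognormal_density(x: np.ndarray, sigma_log: float) -> np.ndarray:
    """Exact density of the z-standardized lognormal at points ``x``.

    If L ~ lognormal(0, sigma) with mean mu and SD s, then X = (L - mu)/s has
    density s * f_L(mu + s x) for mu + s x > 0 and 0 elsewhere.
    """
    mu, s, _, _ = dist.lognormal_theoretical_moments(sigma_log)
    x = np.asarray(x, float)
    raw = mu + s * x
    out = np.zeros_like(x)
    pos = raw > 0
    r = raw[pos]
    out[pos] = (
        s / (r * sigma_log * np.sqrt(2 * np.pi))
        * np.exp(-(np.log(r) ** 2) / (2 * sigma_log**2))
    )
    return out


def density_comparison(
    sigmas: tuple[float, ...] = dist.TABLE1_SIGMAS,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Gaussian density next to standardized-lognormal densities on a grid."""
    if grid is None:
        grid = np.linspace(-4.0, 6.0, 1001)
    grid = np.asarray(grid, float)
    if not np.all(np.isfinite(grid)):
        raise ParameterError("density grid must be finite")
    table = {"x": grid, "gaussian": norm.pdf(grid)}
    for sigma in sigmas:
        table[f"lognormal_{sigma:g}"] = standardized_lognormal_density(grid, sigma)
    return pd.DataFrame(table)


def percentile_cutoff(
    sample: StandardizedSample | np.ndarray,
    level: float,
    n_boot: int = 1000,
    seed: int = 0,
) -> PercentileCutoff:
    """Empirical quantile cut-off (linear interpolation) with bootstrap CI.

    Percentile cut-offs are the distribution-agnostic alternative to
    sigma-based cut-offs: they mean the same thing whatever the tail shape,
    at the price of needing enough observations near the requested level.
    """
    values = sample.values if isinstance(sample, StandardizedSample) else np.asarray(sample, float)
    n = len(values)
    if not 0.0 < level < 1.0:
        raise ParameterError(f"level must be in (0, 1), got {level}")
    if n < 50:
        raise ParameterError(f"need n >= 50 observations, got {n}")
    if n * min(level, 1.0 - level) < 5:
        raise PrecisionError(
            f"level {level} cannot be resolved with n = {n} observations"
        )
    estimate = float(np.quantile(values, level))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.quantile(values[idx], level, axis=1)
    lo, hi = np.quantile(boot, [0.025, 0.975])
    return PercentileCutoff(
        level=level,
        estimate=estimate,
        ci_low=float(min(lo, estimate)),
        ci_high=float(max(hi, estimate)),
        n_boot=n_boot,
    )


_MOMENTS_SEED_NS = 101


def moments_table(
    sigmas: tuple[float, ...] = dist.TABLE1_SIGMAS,
    n: int = 1000,
    reps: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean sample moments of standardized lognormal replicates per sigma.

    For each log-scale SD, draws ``reps`` replicates of size ``n``, computes
    per-replicate skewness g1 and kurtosis ratio b2/3, and reports their
    means next to the exact population values.  At fat-tailed cells the
    sample means sit visibly below the population values — the documented
    downward bias of moment estimators under fat tails.
    """
    rows = []
    for sigma in sigmas:
        spec = DistributionSpec.lognormal(sigma)
        rng = np.random.default_rng(
            np.random.SeedSequence(
                seed, spawn_key=(_MOMENTS_SEED_NS, int(round(sigma * 1_000_000)))
            )
        )
        sum_g1 = 0.0
        sum_b2 = 0.0
        chunk = max(1, int(5_000_000 / n))
        done = 0
        while done < reps:
            m = min(chunk, reps - done)
            block = dist.standardize_rows(dist.sample_matrix(spec, (m, n), rng))
            g1, b2 = dist.row_moments(block)
            sum_g1 += float(g1.sum())
            sum_b2 += float(b2.sum())
            done += m
        theo = dist.lognormal_theoretical_moments(sigma)
        rows.append(
            {
                "sigma_log": sigma,
                "mean_skewness": sum_g1 / reps,
                "mean_kurtosis_ratio": (sum_b2 / reps) / 3.0,
                "theoretical_skewness": theo.skewness,
                "theoretical_kurtosis_ratio": (theo.excess_kurtosis + 3.0) / 3.0,
            }
        )
    return pd.DataFrame(rows)


def write_table(
    frame: pd.DataFrame,
    out: str | Path,
    command: str,
    params: dict,
    version: str | None = None,
) -> Path:
    """Write a CSV plus a JSON sidecar recording how to reproduce it."""
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out, index=False)
    if version is None:
        from . import __version__ as version
    sidecar = out.with_suffix(out.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {"command": command, "params": params, "version": version,
             "out": str(out)},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return sidecar


def read_sidecar(path: str | Path) -> dict:
    """Load a run sidecar written by :func:`write_table`."""
    return json.loads(Path(path).read_text())
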