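"""Between-site comparison statistics.

Reef deployments yield long, autocorrelated, decidedly non-normal records, so
site differences in mean and variance are tested by Monte Carlo randomization:
pool the two sites' values, repeatedly reassign them at random to the two
sites (preserving the original group sizes), and locate the observed
difference in the null distribution of differences.  The same label-shuffling
scheme tests the per-percentile difference between the two distributions, and
a two-sample Kolmogorov–Smirnov test compares the distributions overall.

p-values use the (b+1)/(m+1) convention so they are never exactly zero; the
raw exceedance proportion is also reported.  Per-percentile p-values are NOT
corrected for multiple testing (flagged in the result metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import EmptySeriesError, InsufficientNullError, InvalidConfigError
from .series import EnvironmentalSeries


def _values(x) -> np.ndarray:
    v = x.valid_values() if isinstance(x, EnvironmentalSeries) else np.asarray(x, dtype=float)
    if v.size == 0:
        raise EmptySeriesError("no valid samples")
    return v


@dataclass
class SummaryStats:
    """Deployment summary in the units of the variable."""

    n: int
    mean: float
    sd: float
    range: float
    max: float
    min: float
    q25: float
    q75: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def summarize(series) -> SummaryStats:
    """Summary statistics; quantiles by linear interpolation of order statistics."""
    v = _values(series)
    if v.size < 2:
        raise EmptySeriesError("summarize needs at least 2 valid samples")
    vmax, vmin = float(v.max()), float(v.min())
    return SummaryStats(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)),
        range=vmax - vmin,
        max=vmax,
        min=vmin,
        q25=float(np.percentile(v, 25)),
        q75=float(np.percentile(v, 75)),
    )


@dataclass
class RandomizationResult:
    metric: str
    observed_diff: float
    p_two_tailed: float
    raw_proportion: float
    n_randomizations: int
    seed: int
    null_q025: float
    null_q975: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


_METRICS = {
    "mean": lambda m: m.mean(axis=1),
    "variance": lambda m: m.var(axis=1, ddof=1),
}


def _shuffled_groups(pool: np.ndarray, n_a: int, n_rand: int, rng: np.random.Generator,
                     chunk: int = 250):
    """Yield (a*, b*) matrices of label-shuffled groups, chunked for memory."""
    done = 0
    while done < n_rand:
        k = min(chunk, n_rand - done)
        mat = rng.permuted(np.broadcast_to(pool, (k, pool.size)).copy(), axis=1)
        yield mat[:, :n_a], mat[:, n_a:]
        done += k


def mc_difference_test(
    a, b, metric: str = "mean", n_rand: int = 999, seed: int = 0
) -> RandomizationResult:
    """Two-tailed randomization test of a between-site difference in a metric.

    Null hypothesis: both sites' values come from one statistical population.
    p = (#{|diff*| ≥ |observed|} + 1)/(n_rand + 1), with diff* computed on
    label-shuffled groups that preserve the original group sizes.
    """
    if metric not in _METRICS:
        raise InvalidConfigError(f"metric must be one of {sorted(_METRICS)}")
    if n_rand < 19:
        raise InsufficientNullError("need at least 19 randomizations")
    va, vb = _values(a), _values(b)
    f = _METRICS[metric]
    observed = float(f(va[None, :])[0] - f(vb[None, :])[0])
    pool = np.concatenate([va, vb])
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_rand)
    i = 0
    for ga, gb in _shuffled_groups(pool, va.size, n_rand, rng):
        nulls[i : i + len(ga)] = f(ga) - f(gb)
        i += len(ga)
    n_exceed = int((np.abs(nulls) >= abs(observed)).sum())
    return RandomizationResult(
        metric=metric,
        observed_diff=observed,
        p_two_tailed=(n_exceed + 1) / (n_rand + 1),
        raw_proportion=n_exceed / n_rand,
        n_randomizations=n_rand,
        seed=seed,
        null_q025=float(np.percentile(nulls, 2.5)),
        null_q975=float(np.percentile(nulls, 97.5)),
    )


@dataclass
class PercentileComparison:
    """Per-percentile difference (b − a) with uncorrected two-tailed p-values."""

    percentiles: np.ndarray
    diff: np.ndarray
    p: np.ndarray
    significant_at_05: np.ndarray
    n_randomizations: int
    seed: int
    multiple_testing_correction: str = field(default="none")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "percentile": self.percentiles,
                "diff_b_minus_a": self.diff,
                "p_two_tailed": self.p,
                "significant_at_05": self.significant_at_05.astype(int),
            }
        )


def percentile_difference_test(
    a, b, percentile_grid=None, n_rand: int = 999, seed: int = 0
) -> PercentileComparison:
    """Randomization test of the quantile difference Q_b(q) − Q_a(q) per percentile.

    One shuffle set is reused across the whole percentile grid (the induced
    dependence across percentiles mirrors the data's own); p-values are
    uncorrected, two-tailed, with the +1 convention.
    """
    if n_rand < 19:
        raise InsufficientNullError("need at least 19 randomizations")
    q = np.arange(1, 100, dtype=float) if percentile_grid is None else np.asarray(percentile_grid, float)
    va, vb = _values(a), _values(b)
    observed = np.percentile(vb, q) - np.percentile(va, q)
    pool = np.concatenate([va, vb])
    rng = np.random.default_rng(seed)
    exceed = np.zeros(q.size, dtype=np.int64)
    for ga, gb in _shuffled_groups(pool, va.size, n_rand, rng):
        nd = np.percentile(gb, q, axis=1) - np.percentile(ga, q, axis=1)  # (nq, k)
        exceed += (np.abs(nd) >= np.abs(observed)[:, None]).sum(axis=1)
    p = (exceed + 1) / (n_rand + 1)
    return PercentileComparison(
        percentiles=q, diff=observed, p=p,
        significant_at_05=p <= 0.05,
        n_randomizations=n_rand, seed=seed,
    )


def ks_test(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test: D = sup|ECDF_a − ECDF_b| and the
    asymptotic p-value (two-sample effective n)."""
    va, vb = _values(a), _values(b)
    res = stats.ks_2samp(va, vb, method="asymp")
    return float(res.statistic), float(res.pvalue)


def histogram_densities(a, b, bin_edges) -> dict:
    """Frequency densities of both sites on shared bins (each integrates to 1)."""
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise InvalidConfigError("bin edges must be increasing with at least one bin")
    va, vb = _values(a), _values(b)
    da, _ = np.histogram(va, bins=edges, density=True)
    db, _ = np.histogram(vb, bins=edges, density=True)
    return {"bin_edges": edges, "density_a": da, "density_b": db}
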