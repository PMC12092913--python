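"""Effective-population-size estimators, LD-decay arithmetic, and time conversions.

Census-based Ne uses the harmonic mean of per-timepoint louse counts, which
is dominated by bottlenecks.  Temporal (drift-based) Ne follows the
sampling-plan-II logic for pooled sequencing: the standardized variance of
allele-frequency change between two timepoints, corrected for the two-stage
sampling noise of pool-seq (individuals into the pool, then reads off the
pool), is proportional to t / (2 Ne).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

DAYS_PER_MONTH = 365.25 / 12  # 30.4375


class UnboundedNeWarning(UserWarning):
    """Drift signal too weak relative to sampling noise to bound Ne."""


def harmonic_mean_ne(census: "np.ndarray | list[float]") -> float:
    """Harmonic mean of census counts, a proxy for Ne across bottlenecks.

    Zero counts are excluded with a warning (a harmonic mean with a zero
    term is zero, which would read as extinction rather than a bottleneck).
    """
    counts = np.asarray(census, dtype=float)
    if counts.size == 0:
        raise ValueError("empty census series")
    if np.any(counts < 0):
        raise ValueError("negative census count")
    zeros = counts == 0
    if zeros.any():
        warnings.warn(f"excluding {int(zeros.sum())} zero census counts")
        counts = counts[~zeros]
        if counts.size == 0:
            raise ValueError("all census counts are zero")
    return counts.size / float(np.sum(1.0 / counts))


def ld_decay(d0: float, c: float, t: float) -> float:
    """LD after t generations of recombination at rate c: D_t = D_0 (1-c)^t."""
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"recombination rate c={c} outside [0, 1]")
    if t < 0:
        raise ValueError("negative generation count")
    return d0 * (1.0 - c) ** t
def ld_distance(fraction: float, t: float, chrom_size: float) -> float:
    """Distance d at which LD decays to `fraction` of its initial value in t generations.

    Assumes one recombination event per chromosome per generation, so the
    per-generation recombination rate between sites d apart is c = d / C.
    Inverting D_t/D_0 = (1-c)^t gives d = (1 - fraction^(1/t)) * C.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction={fraction} outside (0, 1]")
    if t < 1:
        raise ValueError("t must be >= 1 generation")
    if chrom_size <= 0:
        raise ValueError("chromosome size must be positive")
    return (1.0 - fraction ** (1.0 / t)) * chrom_size


def generations_elapsed(months: float, generation_days: float = 24.5) -> int:
    """Convert months of experiment time to a whole number of generations.

    Months are 365.25/12 days; the louse generation time defaults to 24.5
    days (egg to adult).  48 months -> 60 generations; 36 months -> 45.
    """
    if months < 0:
        raise ValueError("negative months")
    if generation_days <= 0:
        raise ValueError("generation_days must be positive")
    return round(months * DAYS_PER_MONTH / generation_days)


def divergence_extrapolation(
    observed_delta: float,
    observed_period_years: float,
    target_delta: float,
    mode: str = "floor",
) -> float:
    """Years to reach `target_delta` at the observed linear divergence rate.

    With 18 lumens of luminosity divergence in 4 years, a 65-lumen target
    (the between-species difference) extrapolates to floor(65/4.5) = 14 years.
    """
    if observed_delta <= 0 or observed_period_years <= 0:
        raise ValueError("observed divergence and period must be positive")
    rate = observed_delta / observed_period_years
    years = target_delta / rate
    if mode == "floor":
        return math.floor(years)
    if mode == "nearest":
        return round(years)
    if mode == "exact":
        return years
    raise ValueError(f"unknown mode {mode!r}")


def detectability(s: float, n_loci: int, ne: float) -> bool:
    """Whether per-locus selection on an L-locus trait beats drift: s/L > 1/Ne."""
    if n_loci <= 0:
        raise ValueError("number of trait loci must be >= 1")
    if ne < 2:
        raise ValueError("Ne must be >= 2")
    if s < 0:
        raise ValueError("negative selection coefficient")
    return s / n_loci > 1.0 / ne


def pool_sampling_variance_factor(pool_size: int, depth: float) -> float:
    """1/S* for a pooled sample: Var(read freq) = p(1-p) / S*.

    Two sampling stages: 2n allele copies into the pool, then reads drawn
    from the pool with replacement, giving
    1/S* = 1/(2n) + (1 - 1/(2n)) / R.
    """
    if pool_size < 1 or depth <= 0:
        raise ValueError("pool size and depth must be positive")
    two_n = 2.0 * pool_size
    return 1.0 / two_n + (1.0 - 1.0 / two_n) / depth


@dataclass
class TemporalNeResult:
    ne: float               # inf when the corrected Fc is <= 0
    fc_mean: float          # mean standardized variance across sites
    fc_corrected: float     # after subtracting both sampling terms
    n_sites: int
    unbounded: bool


def temporal_ne(
    freq_t0: np.ndarray,
    freq_t1: np.ndarray,
    generations: int,
    pool_size_t0: int,
    pool_size_t1: int,
    depth_t0: "float | np.ndarray",
    depth_t1: "float | np.ndarray",
) -> TemporalNeResult:
    """Plan-II temporal Ne from pooled allele frequencies at two timepoints.

    Per site, Fc = (x - y)^2 / (z (1 - z)) with z = (x + y)/2.  Its
    expectation is approximately t/(2 Ne) plus one sampling-noise term per
    timepoint; for pool-seq each term is 1/S* from
    :func:`pool_sampling_variance_factor`.  The estimator is

        Ne = t / (2 * (mean Fc - 1/S*_0 - 1/S*_1))

    and is flagged unbounded when the corrected Fc is non-positive (no
    drift signal beyond sampling noise).
    """
    if generations <= 0:
        raise ValueError("generation gap must be positive")
    x = np.asarray(freq_t0, dtype=float)
    y = np.asarray(freq_t1, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency arrays must align site-wise")
    z = (x + y) / 2.0
    informative = (z > 0.0) & (z < 1.0)
    n_sites = int(informative.sum())
    if n_sites == 0:
        raise ValueError("no informative (segregating) sites")
    if n_sites < 100:
        warnings.warn(f"only {n_sites} informative sites; estimate may be unstable")
    fc = (x[informative] - y[informative]) ** 2 / (z[informative] * (1.0 - z[informative]))
    fc_mean = float(np.mean(fc))
    c0 = float(np.mean(pool_sampling_variance_factor(pool_size_t0, np.mean(depth_t0))))
    c1 = float(np.mean(pool_sampling_variance_factor(pool_size_t1, np.mean(depth_t1))))
    fc_corr = fc_mean - c0 - c1
    if fc_corr <= 0:
        warnings.warn("corrected Fc <= 0; Ne unbounded", UnboundedNeWarning)
        return TemporalNeResult(math.inf, fc_mean, fc_corr, n_sites, True)
    return TemporalNeResult(generations / (2.0 * fc_corr), fc_mean, fc_corr, n_sites, False)
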