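"""Per-site tests of allele-frequency differentiation and locus calling.

Two tests are provided.  pFST is a likelihood-ratio test contrasting the
hypothesis that target (AFT) and background (AFB) read counts share one
underlying allele frequency against separate frequencies, with reads drawn
through a genotyping-error channel: P(alt read) = p(1-eps) + (1-p)eps.
Because the channel compresses frequencies into [eps, 1-eps], low-coverage
sites cannot produce extreme likelihood ratios, which attenuates their
significance by construction.  The Cochran-Mantel-Haenszel test combines
2x2 allele-count tables across replicate populations to find consistent
frequency change.

Downstream: Fisher-method sliding-window combination, Benjamini-Hochberg
FDR, outlier flagging (top statistic fraction and/or q < alpha), merging of
nearby significant sites into putative loci, and subtraction of loci that
replicate in the matched impaired-preening (no-selection) contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .overlap_perm import IntervalSet, overlaps_any

log = logging.getLogger(__name__)


@dataclass
class ContrastSpec:
    """A target-vs-background population contrast for differentiation tests."""

    target: list
    background: list
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if set(self.target) & set(self.background):
            raise ValueError("target and background populations must be disjoint")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("genotyping-error rate must be in [0, 0.5)")


def _binom_loglik(alt: np.ndarray, n: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood up to the constant binomial coefficient."""
    f = np.clip(f, 1e-300, 1 - 1e-300)
    return alt * np.log(f) + (n - alt) * np.log(1 - f)


def pfst_sites(
    target_ref: np.ndarray,
    target_alt: np.ndarray,
    background_ref: np.ndarray,
    background_alt: np.ndarray,
    epsilon: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pFST over sites; returns (statistic, p, zero_depth_flag).

    The error channel maps the true alt frequency p to the read-alt
    probability f(p) = eps + p(1 - 2 eps), a monotone map of [0,1] onto
    [eps, 1-eps].  The MLE of f on each side (and of the shared f under
    the null, the pooled proportion) is the observed read fraction clamped
    into [eps, 1-eps]; the statistic is 2(lnL1 - lnL0) ~ chi2(1) under H0.
    Sites with zero depth on either side get p = 1 and a flag.
    """
    if not 0.0 <= epsilon < 0.5:
        raise ValueError("genotyping-error rate must be in [0, 0.5)")
    tr, ta = np.asarray(target_ref, float), np.asarray(target_alt, float)
    br, ba = np.asarray(background_ref, float), np.asarray(background_alt, float)
    nt, nb = tr + ta, br + ba
    zero = (nt == 0) | (nb == 0)
    nt_s, nb_s = np.maximum(nt, 1), np.maximum(nb, 1)
    lo, hi = epsilon, 1.0 - epsilon
    ft = np.clip(ta / nt_s, lo, hi)
    fb = np.clip(ba / nb_s, lo, hi)
    f0 = np.clip((ta + ba) / (nt_s + nb_s), lo, hi)
    l1 = _binom_loglik(ta, nt, ft) + _binom_loglik(ba, nb, fb)
    l0 = _binom_loglik(ta, nt, f0) + _binom_loglik(ba, nb, f0)
    stat = np.maximum(2.0 * (l1 - l0), 0.0)
    p = stats.chi2.sf(stat, df=1)
    stat = np.where(zero, 0.0, stat)
    p = np.where(zero, 1.0, p)
    return stat, p, zero


def pfst_site(
    target: tuple, background: tuple, epsilon: float = 0.01
) -> tuple[float, float]:
    """pFST for one site; ``target`` and ``background`` are (ref, alt) read counts."""
    if sum(target) < 1 or sum(background) < 1:
        warnings.warn("zero-depth side: p set to 1")
    stat, p, _ = pfst_sites(
        np.array([target[0]]), np.array([target[1]]),
        np.array([background[0]]), np.array([background[1]]), epsilon,
    )
    return float(stat[0]), float(p[0])


def cmh_sites(tables: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cochran-Mantel-Haenszel over sites; ``tables`` is
    (n_sites, K, 2, 2) with rows = populations and columns = alleles.

    Classical form without continuity correction:
    T = (sum_k (a_k - E_k))^2 / sum_k Var_k with hypergeometric E and Var;
    p from chi2(1).  Degenerate strata (a zero margin) contribute nothing
    and are dropped with a log message.
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim == 3:
        t = t[None]
    a = t[:, :, 0, 0]
    row1 = t[:, :, 0, :].sum(axis=2)
    row2 = t[:, :, 1, :].sum(axis=2)
    col1 = t[:, :, :, 0].sum(axis=2)
    col2 = t[:, :, :, 1].sum(axis=2)
    n = row1 + row2
    degenerate = (row1 == 0) | (row2 == 0) | (col1 == 0) | (col2 == 0) | (n <= 1)
    if degenerate.any():
        log.info("cmh: dropping %d degenerate strata", int(degenerate.sum()))
    ok = ~degenerate
    n_s = np.where(ok, n, 1.0)
    e = np.where(ok, row1 * col1 / n_s, 0.0)
    var = np.where(ok, row1 * row2 * col1 * col2 / (n_s ** 2 * np.maximum(n_s - 1, 1)), 0.0)
    num = (np.where(ok, a, 0.0) - e).sum(axis=1) ** 2
    den = var.sum(axis=1)
    stat = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    p = np.where(den > 0, stats.chi2.sf(stat, df=1), 1.0)
    return stat, p


def cmh_site(tables: "Sequence | np.ndarray") -> tuple[float, float]:
    """CMH for one site from K stratified 2x2 tables."""
    t = np.asarray(tables, dtype=float)
    if t.ndim != 3 or t.shape[1:] != (2, 2):
        raise ValueError("expected K stratified 2x2 tables")
    stat, p = cmh_sites(t[None])
    return float(stat[0]), float(p[0])


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values, original order."""
    p = np.asarray(pvals, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p values are not adjustable")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class WindowResult:
    table: pd.DataFrame  # chrom, start, end, n_sites, statistic, p


def window_fisher(
    chroms: np.ndarray,
    positions: np.ndarray,
    pvals: np.ndarray,
    window_size: int = 10_000,
    step: int = 50_000,
) -> WindowResult:
    """Fisher-method combination of site p values in sliding windows.

    Windows start every ``step`` bp from position 1 on each chromosome and
    span ``window_size`` bp; per window X = -2 sum ln p over its k member
    sites is referred to chi2(2k).  Empty windows emit no record.  The
    literal configuration from the source analysis (10 kb windows every
    50 kb) leaves most sites outside all windows, which is surfaced as a
    warning when step > window_size.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    if step > window_size:
        warnings.warn(
            f"step ({step}) exceeds window size ({window_size}); "
            "most sites fall outside all windows"
        )
    chroms = np.asarray(chroms, dtype=object)
    positions = np.asarray(positions, dtype=np.int64)
    pvals = np.asarray(pvals, dtype=float)
    rows = []
    for c in dict.fromkeys(chroms):
        m = chroms == c
        pos, pv = positions[m], pvals[m]
        if pos.size == 0:
            continue
        last = int(pos.max())
        start = 1
        while start <= last:
            in_win = (pos >= start) & (pos < start + window_size)
            k = int(in_win.sum())
            if k:
                x = -2.0 * np.sum(np.log(np.clip(pv[in_win], 1e-300, 1.0)))
                rows.append((c, start, start + window_size, k, x,
                             float(stats.chi2.sf(x, df=2 * k))))
            start += step
    return WindowResult(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_sites", "statistic", "p"]
    ))


@dataclass
class ScanResult:
    """Per-site scan statistics plus outlier flags."""

    sites: pd.DataFrame          # chrom, pos, statistic, p, q, top, significant
    windows: "pd.DataFrame | None" = None
    test: str = ""

    @classmethod
    def from_stats(
        cls,
        chroms: np.ndarray,
        positions: np.ndarray,
        statistic: np.ndarray,
        pvals: np.ndarray,
        test: str = "",
        top_fraction: float = 0.001,
        q_alpha: float = 0.05,
    ) -> "ScanResult":
        q = bh_fdr(pvals)
        df = pd.DataFrame({
            "chrom": np.asarray(chroms, dtype=object),
            "pos": np.asarray(positions, dtype=np.int64),
            "statistic": np.asarray(statistic, dtype=float),
            "p": np.asarray(pvals, dtype=float),
            "q": q,
        })
        df["top"] = top_fraction_flags(df["statistic"].to_numpy(), top_fraction)
        df["significant"] = df["q"] < q_alpha
        return cls(df, None, test)


def top_fraction_flags(statistic: np.ndarray, top_fraction: float) -> np.ndarray:
    """Flag the highest ``top_fraction`` of sites by statistic, keeping all
    sites tied at the boundary value."""
    if not 0.0 <= top_fraction <= 1.0:
        raise ValueError("top_fraction must be in [0, 1]")
    stat = np.asarray(statistic, dtype=float)
    n = stat.size
    k = int(round(top_fraction * n))
    if k == 0:
        return np.zeros(n, dtype=bool)
    threshold = np.sort(stat)[n - k]
    return stat >= threshold


def call_and_merge_loci(
    scan: ScanResult,
    chrom_sizes: dict,
    top_fraction: float = 0.001,
    q_alpha: float = 0.05,
    merge_distance: int = 500,
    rule: str = "intersection",
    label: str = "",
) -> IntervalSet:
    """Call outlier sites and merge nearby ones into putative loci.

    ``rule``: 'intersection' (default; top-fraction AND q < alpha, the
    dual-threshold outlier definition), 'union', 'top', or 'q'.  Passing
    sites within ``merge_distance`` bp on one chromosome union into a
    single locus interval (0-based half-open; a lone site spans 1 bp).
    """
    df = scan.sites
    top = top_fraction_flags(df["statistic"].to_numpy(), top_fraction)
    sig = bh_fdr(df["p"].to_numpy()) < q_alpha
    if rule == "intersection":
        passing = top & sig
    elif rule == "union":
        passing = top | sig
    elif rule == "top":
        passing = top
    elif rule == "q":
        passing = sig
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    chroms, starts, ends = [], [], []
    sub = df.loc[passing, ["chrom", "pos"]].sort_values(["chrom", "pos"])
    for c, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        i = 0
        while i < len(pos):
            j = i
            while j + 1 < len(pos) and pos[j + 1] - pos[j] <= merge_distance:
                j += 1
            chroms.append(c); starts.append(int(pos[i]) - 1); ends.append(int(pos[j]))
            i = j + 1
    return IntervalSet(np.array(chroms, dtype=object), np.array(starts, dtype=np.int64),
                       np.array(ends, dtype=np.int64), dict(chrom_sizes), label)


def subtract_impaired(
    preening_loci: IntervalSet, impaired_loci: IntervalSet
) -> IntervalSet:
    """Drop preening-treatment loci that replicate in the matched
    impaired-preening (selection-off) contrast; what remains is attributed
    to preening-mediated selection."""
    if len(impaired_loci) == 0:
        return preening_loci
    keep = ~overlaps_any(preening_loci, impaired_loci)
    return IntervalSet(
        preening_loci.chroms[keep], preening_loci.starts[keep],
        preening_loci.ends[keep], preening_loci.chrom_sizes,
        preening_loci.label,
    )
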