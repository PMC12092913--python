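"""Allele-frequency trajectories: polarization, slope fits, fixation scoring.

A trajectory is the read support for one tracked allele in one population
across timepoints (in generations).  Sites are polarized toward whichever
allele is more common in experimental than control populations at a
reference month, so selected alleles trend upward by construction at the
reference point — a bias that is absent at other timepoints under
neutrality (regression to the mean).

Slopes are fitted twice: a least-squares line on frequencies, and a
binomial GLM with logit link on per-read allele indicators, whose p value
scales with coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning


@dataclass
class TrajectorySeries:
    """Tracked-allele read counts over timepoints for one site/population."""

    site_id: str
    pop_id: str
    generations: np.ndarray
    counts: np.ndarray          # tracked-allele reads per timepoint
    totals: np.ndarray
    polarity: str = "alt"       # which allele is tracked

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        if not (len(self.generations) == len(self.counts) == len(self.totals)):
            raise ValueError("timepoint arrays must align")
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.counts > self.totals) or np.any(self.counts < 0):
            raise ValueError("counts must lie in [0, total]")

    @property
    def frequencies(self) -> np.ndarray:
        """Tracked-allele frequency; NaN where depth is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.totals > 0,
                            self.counts / np.maximum(self.totals, 1), np.nan)

    def observed(self) -> "TrajectorySeries":
        """Drop zero-depth timepoints (they are omitted from fits, not imputed)."""
        m = self.totals > 0
        return TrajectorySeries(self.site_id, self.pop_id,
                                self.generations[m], self.counts[m],
                                self.totals[m], self.polarity)


@dataclass
class SlopeFit:
    slope: float
    intercept: float
    p_value: float
    method: str                  # {"ols", "binomial-glm"}
    separated: bool = False      # complete separation in the GLM


def polarize(
    experimental_freq: float, control_freq: float
) -> str:
    """Choose the tracked allele: 'alt' if the alternative allele is more
    common in experimental than control populations at the reference month,
    else 'ref'.  Exact ties break toward 'alt' (deterministic)."""
    if np.isnan(experimental_freq) or np.isnan(control_freq):
        raise ValueError("missing reference-month frequency")
    return "alt" if experimental_freq >= control_freq else "ref"


def polarize_sites(
    exp_ref: np.ndarray, exp_alt: np.ndarray,
    ctrl_ref: np.ndarray, ctrl_alt: np.ndarray,
) -> np.ndarray:
    """Vectorized polarization from summed reference-month read counts;
    returns an array of 'alt'/'ref' per site."""
    with np.errstate(invalid="ignore", divide="ignore"):
        fe = exp_alt / np.maximum(exp_ref + exp_alt, 1)
        fc = ctrl_alt / np.maximum(ctrl_ref + ctrl_alt, 1)
    return np.where(fe >= fc, "alt", "ref").astype(object)


def fit_slope_ols(series: TrajectorySeries, time_axis: str = "generations") -> SlopeFit:
    """Least-squares line frequency ~ time; exact slope and intercept.

    ``time_axis`` may be 'generations' (default) or scaled to months via
    the series' generation values divided by a caller-supplied factor; the
    series carries generations, so callers wanting months rescale first.
    """
    obs = series.observed()
    if len(obs.generations) < 2:
        raise ValueError("need >= 2 timepoints with data for a slope fit")
    x, y = obs.generations, obs.frequencies
    if np.allclose(y, y[0]):
        return SlopeFit(0.0, float(y[0]), 1.0, "ols")
    res = stats.linregress(x, y)
    return SlopeFit(float(res.slope), float(res.intercept), float(res.pvalue), "ols")


def fit_slope_glm(series: TrajectorySeries, p_value: str = "wald") -> SlopeFit:
    """Binomial GLM of the per-read tracked-allele indicator on generation.

    Equivalent to coding each read as 1 (tracked allele) or 0 and fitting
    allele ~ generation with a logit link by IRLS; the slope is the
    generation coefficient on the log-odds scale.  ``p_value`` is 'wald'
    (default) or 'lrt'.  Complete separation is flagged and p set to NaN
    rather than trusting a divergent Wald statistic.
    """
    obs = series.observed()
    if len(obs.generations) < 2:
        raise ValueError("need >= 2 timepoints with data for a slope fit")
    endog = np.column_stack([obs.counts, obs.totals - obs.counts])
    exog = sm.add_constant(obs.generations)
    try:
        with warnings.catch_warnings():
            # statsmodels warns on any zero-deviance fit; true separation is
            # detected below from the parameter estimates themselves
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit(
                tol=1e-8, maxiter=200
            )
    except PerfectSeparationError:
        return SlopeFit(np.nan, np.nan, np.nan, "binomial-glm", separated=True)
    slope = float(fit.params[1])
    intercept = float(fit.params[0])
    if abs(slope) > 25 or not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
        # slope running to the boundary: separation in practice
        return SlopeFit(slope, intercept, np.nan, "binomial-glm", separated=True)
    if p_value == "wald":
        p = float(fit.pvalues[1])
    elif p_value == "lrt":
        null = sm.GLM(endog, exog[:, :1], family=sm.families.Binomial()).fit(tol=1e-8)
        lr = 2.0 * (fit.llf - null.llf)
        p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    else:
        raise ValueError("p_value must be 'wald' or 'lrt'")
    return SlopeFit(slope, intercept, p, "binomial-glm")


def score_fixation(
    series: TrajectorySeries, tolerance: float = 0.0
) -> tuple[str, "int | None"]:
    """Classify a trajectory as fixed / lost / segregating.

    Fixed: the tracked allele reaches frequency 1.0 at some timepoint and
    stays at 1.0 for every later observed timepoint; lost is symmetric at
    0.0; anything else segregates.  Returns (state, index of the first
    fixation/loss timepoint in the observed series, or None).  A nonzero
    ``tolerance`` relaxes the boundaries to >= 1 - tolerance / <= tolerance.
    """
    obs = series.observed()
    f = obs.frequencies
    if f.size == 0:
        raise ValueError("empty trajectory")
    hi, lo = 1.0 - tolerance, tolerance
    for state, cond in (("fixed", f >= hi), ("lost", f <= lo)):
        idx = np.flatnonzero(cond)
        if idx.size and cond[idx[0]:].all():
            return state, int(idx[0])
    return "segregating", None


def cumulative_fixations(
    fix_results: Sequence[tuple[str, "int | None"]], n_timepoints: int
) -> np.ndarray:
    """Count of trajectories fixed or lost by each timepoint index."""
    curve = np.zeros(n_timepoints, dtype=np.int64)
    for state, idx in fix_results:
        if state in ("fixed", "lost") and idx is not None and np.isfinite(idx):
            curve[int(idx):] += 1
    return curve


def compare_slopes_tukey(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """One-way ANOVA with Tukey HSD pairwise comparisons of slope groups.

    Returns a frame with group1, group2, mean difference, and the
    studentized-range adjusted p value per pair.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    labels, values = [], []
    for name, vals in groups.items():
        vals = list(vals)
        if len(vals) < 2:
            raise ValueError(f"group {name!r} needs >= 2 values")
        labels += [name] * len(vals)
        values += vals
    res = pairwise_tukeyhsd(np.asarray(values, float), np.asarray(labels, object))
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return frame.rename(columns={"p-adj": "p_adj"})


def folded_sfs(
    ref_counts: np.ndarray, alt_counts: np.ndarray, n_bins: int = 10
) -> np.ndarray:
    """Histogram of minor-allele read frequencies over (0, 0.5].

    Zero-depth sites are excluded; the histogram sums to the number of
    sites with data.  Bin edges are uniform on [0, 0.5], the last bin
    closed so an exactly-0.5 site lands in the top bin.
    """
    ref = np.asarray(ref_counts, float)
    alt = np.asarray(alt_counts, float)
    tot = ref + alt
    ok = tot > 0
    maf = np.minimum(ref[ok], alt[ok]) / tot[ok]
    hist, _ = np.histogram(maf, bins=np.linspace(0.0, 0.5, n_bins + 1))
    return hist


def greatest_change_interval(series: TrajectorySeries) -> tuple[int, int, float]:
    """Consecutive-timepoint pair with the largest |frequency change|.

    Returns (i, j, delta) with j = i + 1 over the observed timepoints and
    delta signed; the earliest pair wins ties.
    """
    obs = series.observed()
    f = obs.frequencies
    if f.size < 2:
        raise ValueError("need >= 2 timepoints")
    d = np.diff(f)
    i = int(np.argmax(np.abs(d)))
    return i, i + 1, float(d[i])
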