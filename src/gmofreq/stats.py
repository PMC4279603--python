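"""Frequency distributions and the population statistics panel.

The 5000 GMO percentages of one (setting, replicate-number) cell are treated
as the entire population, not a sample — all moments therefore use the
population convention (divisor n; the spreadsheet functions AVERAGE, STDEVP).
The panel comprises:

* mean, population SD, relative SD (100*s/mean),
* relative absolute deviation from the nominal value (trueness),
* empirical population skewness  v = (1/n) * sum(((x_i - mean)/s)**3),
* a simplified chi-square comparison against the Gaussian normal
  distribution over the frequency classes: chi2 = sum(d**2/m) with d = n - m
  per class, deliberately WITHOUT merging marginal classes whose expected
  count falls below 10; the upper-tail probability (CHIDIST semantics) is
  displayed as a percentage,
* the >= 95 % cut-off summary of the histogram: the largest count threshold
  whose classes jointly hold at least the target share of values, reported as
  middle class (U_last + U_first)/2 and half range (U_last - U_first)/2 over
  the included classes' upper limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .quantify import ConversionConfig
from .resampling import GmoPopulation, ResamplingPlan


class StatsError(ValueError):
    pass


DEFAULT_N_CLASSES = 20
DEFAULT_COVERAGE = 0.95
DEFAULT_RSD_THRESHOLD = 15.0  # percent


@dataclass
class FrequencyDistribution:
    """Equal-width frequency classes over a population of values.

    Classes are half-open on the right edge except the last, which is closed,
    so the maximum falls in the last class.  ``upper_limits`` are the class
    labels used on histogram axes.
    """

    class_edges: np.ndarray  # n_classes + 1 ascending edges, %
    counts: np.ndarray       # per-class occupancy, symbol n
    n_total: int

    @property
    def n_classes(self) -> int:
        return len(self.counts)

    @property
    def upper_limits(self) -> np.ndarray:
        return self.class_edges[1:]

    @property
    def class_width(self) -> float:
        return float(self.class_edges[1] - self.class_edges[0])


@dataclass
class PopulationStats:
    mean: float
    sd_population: float
    rsd: float                    # %, 100*s/mean
    skewness: float
    rel_abs_deviation: float      # %, vs nominal
    chi_square: float
    chi_df: int
    chi_p: float                  # probability in [0, 1]; displayed as %


@dataclass
class CutoffSummary:
    coverage_target: float
    count_threshold: int          # the dashed-line height
    included_upper_limits: np.ndarray
    achieved_coverage: float      # fraction of all values inside
    middle_class: float           # (U_last + U_first)/2
    half_range: float             # (U_last - U_first)/2

    @property
    def included_class_range(self) -> tuple[float, float]:
        return float(self.included_upper_limits[0]), float(self.included_upper_limits[-1])


def bin_values(values: Sequence[float], n_classes: int = DEFAULT_N_CLASSES) -> FrequencyDistribution:
    """Equal-width classes spanning [min, max] of the population.

    A degenerate all-equal population falls back to unit-width classes with
    only the first occupied (with a warning), mirroring the plate case where
    all replicates combined collapse the variation.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError("cannot bin an empty population")
    if n_classes < 2:
        raise StatsError("need at least 2 classes")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        warnings.warn(
            "all population values identical; using unit-width fallback classes",
            stacklevel=2,
        )
        edges = lo - 0.5 + np.arange(n_classes + 1, dtype=float)
    else:
        edges = np.linspace(lo, hi, n_classes + 1)
    counts, _ = np.histogram(v, bins=edges)
    return FrequencyDistribution(class_edges=edges, counts=counts, n_total=int(v.size))


def population_sd(values: Sequence[float]) -> float:
    """Standard deviation with divisor n (STDEVP), never n - 1."""
    v = np.asarray(values, dtype=float)
    if v.size and v.max() == v.min():
        # exact zero for a constant population (np.std can leave ~1e-17
        # from the mean's last-ulp rounding)
        return 0.0
    return float(np.std(v, ddof=0))


def empirical_skewness(values: Sequence[float]) -> float:
    """v = (1/n) * sum(((x_i - mean)/s)**3) with s the population SD."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise StatsError("skewness needs at least 2 values")
    s = population_sd(v)
    if s == 0:
        raise StatsError("skewness undefined for zero population SD")
    return float(np.mean(((v - v.mean()) / s) ** 3))


def chi_square_normality(
    dist: FrequencyDistribution, mean: float, sd: float, df: int | None = None
) -> tuple[float, int, float]:
    """Simplified chi-square test of the binned population against
    Gaussian(mean, sd).

    Expected counts m come from the exact Gaussian probability mass of each
    class interval (CDF differences) times n_total, with the first class's
    lower edge extended to -inf and the last class's upper edge to +inf so no
    mass is lost.  Marginal classes with m < 10 are NOT merged.  Default
    degrees of freedom: n_classes - 3 (mean and SD estimated from the data).
    Returns (chi2, df, upper-tail p).
    """
    if dist.n_classes < 4:
        raise StatsError("chi-square normality check needs >= 4 classes")
    if sd <= 0:
        raise StatsError("chi-square normality check needs sd > 0")
    edges = dist.class_edges.astype(float).copy()
    edges[0], edges[-1] = -np.inf, np.inf
    lo, hi = edges[:-1], edges[1:]
    # class mass: CDF difference, evaluated through the survival function for
    # classes right of the mean so far-tail masses keep full precision
    mass = np.where(
        lo >= mean,
        _st.norm.sf(lo, mean, sd) - _st.norm.sf(hi, mean, sd),
        _st.norm.cdf(hi, mean, sd) - _st.norm.cdf(lo, mean, sd),
    )
    expected = mass * dist.n_total
    if np.any(expected == 0):
        raise StatsError(
            "a class has zero expected count even with open tails; "
            "reduce the number of classes"
        )
    d = np.asarray(dist.counts, dtype=float) - expected
    chi2 = float(np.sum(d * d / expected))
    if df is None:
        df = dist.n_classes - 3
    if df < 1:
        raise StatsError("non-positive chi-square degrees of freedom")
    p = float(_st.chi2.sf(chi2, df))
    return chi2, int(df), p


def population_stats(
    values: Sequence[float],
    nominal: float,
    dist: FrequencyDistribution | None = None,
    chi_df: int | None = None,
) -> PopulationStats:
    """The full statistics panel for one population.

    ``nominal`` is the certified GM content (%) the trueness measure refers
    to.  If ``dist`` is omitted the chi-square entries are computed on a
    default binning of the values; for a degenerate population (zero SD) the
    skewness and chi-square entries are reported as NaN rather than failing
    the whole panel.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError("empty population")
    if nominal <= 0:
        raise StatsError("nominal value must be > 0")
    mean = float(v.mean())
    sd = population_sd(v)
    if mean == 0:
        raise StatsError("relative SD undefined for zero mean")
    rsd = 100.0 * sd / mean
    rel_dev = 100.0 * abs(mean - nominal) / nominal
    if sd == 0:
        skew, chi2, df, p = float("nan"), float("nan"), 0, float("nan")
    else:
        skew = empirical_skewness(v)
        if dist is None:
            dist = bin_values(v)
        chi2, df, p = chi_square_normality(dist, mean, sd, df=chi_df)
    return PopulationStats(
        mean=mean,
        sd_population=sd,
        rsd=rsd,
        skewness=skew,
        rel_abs_deviation=rel_dev,
        chi_square=chi2,
        chi_df=df,
        chi_p=p,
    )


def cutoff_summary(
    dist: FrequencyDistribution, coverage_target: float = DEFAULT_COVERAGE
) -> CutoffSummary:
    """Largest count threshold c whose classes (count >= c) jointly hold at
    least ``coverage_target`` of all values; ties at the threshold are all
    included (dashed-line semantics)."""
    counts = np.asarray(dist.counts)
    need = coverage_target * dist.n_total
    threshold = None
    for c in sorted(np.unique(counts[counts > 0]), reverse=True):
        if counts[counts >= c].sum() >= need:
            threshold = int(c)
            break
    if threshold is None:  # c = 1 always qualifies for a non-empty population
        threshold = 1
    included = counts >= threshold
    uppers = dist.upper_limits[included]
    achieved = float(counts[included].sum() / dist.n_total)
    u_first, u_last = float(uppers[0]), float(uppers[-1])
    return CutoffSummary(
        coverage_target=coverage_target,
        count_threshold=threshold,
        included_upper_limits=uppers,
        achieved_coverage=achieved,
        middle_class=(u_last + u_first) / 2.0,
        half_range=(u_last - u_first) / 2.0,
    )


@dataclass
class SweepCell:
    """All derived results of one (setting, replicate-number) cell."""

    setting_id: str
    k: int
    distribution: FrequencyDistribution
    stats: PopulationStats
    cutoff: CutoffSummary


def replicate_sweep(
    populations: Iterable[GmoPopulation],
    nominal: float,
    n_classes: int = DEFAULT_N_CLASSES,
    coverage_target: float = DEFAULT_COVERAGE,
    chi_df: int | None = None,
) -> dict[tuple[str, int], SweepCell]:
    """Bin and summarise every population of the (setting x k) grid."""
    grid: dict[tuple[str, int], SweepCell] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate k = pool-size cells
        for pop in populations:
            dist = bin_values(pop.values, n_classes=n_classes)
            stats = population_stats(pop.values, nominal, dist=dist, chi_df=chi_df)
            cut = cutoff_summary(dist, coverage_target=coverage_target)
            grid[(pop.setting_id, pop.k)] = SweepCell(
                setting_id=pop.setting_id, k=pop.k, distribution=dist, stats=stats, cutoff=cut
            )
    return grid


def min_replicates_for_rsd(
    grid: Mapping[tuple[str, int], SweepCell],
    rsd_threshold: float = DEFAULT_RSD_THRESHOLD,
) -> int | None:
    """Smallest k whose relative SD is at or below the threshold for ALL
    settings; None if no k on the grid qualifies."""
    settings = sorted({s for s, _ in grid})
    ks = sorted({k for _, k in grid})
    for k in ks:
        if all(grid[(s, k)].stats.rsd <= rsd_threshold for s in settings):
            return k
    return None


def summary_table(grid: Mapping[tuple[str, int], SweepCell]) -> pd.DataFrame:
    """One row per (setting, k): the exportable panel, percentages on the
    scale they are displayed (chi_p in %)."""
    rows = []
    for (sid, k), cell in sorted(grid.items()):
        st, cut = cell.stats, cell.cutoff
        rows.append(
            {
                "setting": sid,
                "k": k,
                "mean": st.mean,
                "sd": st.sd_population,
                "rsd": st.rsd,
                "skewness": st.skewness,
                "chi_p": 100.0 * st.chi_p,
                "rel_abs_deviation": st.rel_abs_deviation,
                "middle_class": cut.middle_class,
                "half_range": cut.half_range,
                "achieved_coverage": cut.achieved_coverage,
            }
        )
    return pd.DataFrame(rows)
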