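"""Demographic statistics for lifespan, stress-resistance and fecundity assays.

The suite covers the standard toolbox of a fly-longevity study: Kaplan-Meier
style quantiles with an averaging (type-2) convention so that half-day medians
are representable, Gompertz hazard fitting and the mortality-rate doubling
time (MRDT), log-rank and two-sample Kolmogorov-Smirnov comparisons of
survival curves, the Wang-Allison 2x2 test for maximum lifespan, Fisher's
exact test, Student's t for fecundity, and death calling from activity-monitor
bins (death is placed at the start of the first 30-minute bin after the last
recorded movement).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "SurvivalSample",
    "LifespanSummary",
    "TestResult",
    "GompertzFit",
    "call_death_times",
    "survival_percentile",
    "stress_percentiles",
    "summarize_lifespan",
    "fit_gompertz",
    "fit_gompertz_hazard",
    "logrank_test",
    "ks_test_survival",
    "wang_allison_test",
    "fisher_exact_2x2",
    "relative_difference",
    "fecundity_ttest",
]


@dataclass
class SurvivalSample:
    """Event times with censoring flags for one cohort."""

    times: np.ndarray
    events: np.ndarray  # True = death observed, False = right-censored
    label: str = ""
    sex: str = ""
    replicate: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events, dtype=bool)
        if self.times.shape != self.events.shape:
            raise ValueError("times and events must have equal length")
        if (self.times <= 0).any():
            raise ValueError("event times must be positive")

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def death_times(self) -> np.ndarray:
        return self.times[self.events]

    @property
    def fully_observed(self) -> bool:
        return bool(self.events.all())


@dataclass
class LifespanSummary:
    median: float
    q90: float
    mrdt: float  # days; inf when the fitted Gompertz slope is ~0
    n: int
    gompertz_a: float = np.nan
    gompertz_g: float = np.nan


@dataclass
class TestResult:
    name: str
    statistic: float
    p_value: float
    table: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass
class GompertzFit:
    a: float  # baseline hazard per day
    g: float  # hazard slope per day

    @property
    def mrdt(self) -> float:
        return np.log(2) / self.g if self.g > 1e-9 else np.inf


# ---------------------------------------------------------------------------
# death calling from activity monitors


def call_death_times(
    activity: pd.DataFrame | np.ndarray,
    bin_width: float = 0.5,
    label: str = "",
) -> SurvivalSample:
    """Call death times from a fly x 30-minute-bin activity matrix.

    Death is assigned to the start of the first bin after the last bin with
    non-zero activity (equivalently ``(last_active_bin + 1) * bin_width``).
    A fly still active in the final bin is right-censored at assay end.
    An all-zero row gets a death at the first bin boundary, with a warning.
    """
    arr = np.asarray(activity, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] < 1:
        raise ValueError("activity matrix needs at least one bin")
    if (arr < 0).any():
        raise ValueError("activity counts must be non-negative")
    n_flies, n_bins = arr.shape
    assay_end = n_bins * bin_width
    times = np.empty(n_flies)
    events = np.empty(n_flies, dtype=bool)
    for i in range(n_flies):
        nz = np.nonzero(arr[i])[0]
        if nz.size == 0:
            log.warning("fly %d has no recorded activity; death set to first bin boundary", i)
            times[i] = bin_width
            events[i] = True
        elif nz[-1] == n_bins - 1:
            times[i] = assay_end
            events[i] = False
        else:
            times[i] = (nz[-1] + 1) * bin_width
            events[i] = True
    return SurvivalSample(times=times, events=events, label=label)


# ---------------------------------------------------------------------------
# quantiles and summaries


def survival_percentile(sample: SurvivalSample, q: float) -> float:
    """Age by which a fraction ``q`` of the cohort has died.

    Uncensored samples use the averaging (type-2) empirical quantile, so an
    even split yields the mid-point between the two straddling order
    statistics (medians like 58.5 days are representable).  Censored samples
    use the Kaplan-Meier curve: the first time at which S(t) <= 1-q.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    if not sample.events.any():
        raise ValueError("no uncensored events; percentile undefined")
    if sample.fully_observed:
        return float(
            np.quantile(sample.times, q, method="averaged_inverted_cdf")
        )
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter()
    km.fit(sample.times, event_observed=sample.events)
    sf = km.survival_function_.iloc[:, 0]
    below = sf[sf <= 1.0 - q + 1e-12]
    if below.empty:
        raise ValueError(f"KM curve never reaches survival {1-q:.3f} (heavy censoring)")
    return float(below.index[0])


def stress_percentiles(
    sample: SurvivalSample, levels: tuple[float, ...] = (0.25, 0.5, 0.75, 0.9)
) -> dict[float, float]:
    """Survival-time percentiles (default 25/50/75/90%) for a stress assay."""
    out = {q: survival_percentile(sample, q) for q in levels}
    vals = [out[q] for q in sorted(out)]
    assert all(b >= a for a, b in zip(vals, vals[1:])), "percentiles must be monotone"
    return out


def summarize_lifespan(
    sample: SurvivalSample, bin_width: float = 7.0, min_events: int = 10
) -> LifespanSummary:
    """Median, age of 90% mortality, and MRDT for a lifespan cohort."""
    n_events = int(sample.events.sum())
    if n_events < min_events:
        raise ValueError(
            f"lifespan summary needs >= {min_events} deaths, got {n_events}"
        )
    fit = fit_gompertz(sample, bin_width=bin_width)
    return LifespanSummary(
        median=survival_percentile(sample, 0.5),
        q90=survival_percentile(sample, 0.9),
        mrdt=fit.mrdt,
        n=sample.n,
        gompertz_a=fit.a,
        gompertz_g=fit.g,
    )


# ---------------------------------------------------------------------------
# Gompertz hazard


def _life_table(times: np.ndarray, bin_width: float):
    """Deaths and at-risk numbers on a regular age grid starting at 0."""
    n = times.size
    n_bins = int(np.ceil(times.max() / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    deaths, _ = np.histogram(times, bins=edges)
    at_risk = n - np.concatenate(([0], np.cumsum(deaths)[:-1]))
    mids = edges[:-1] + bin_width / 2.0
    return mids, deaths.astype(float), at_risk.astype(float)


def fit_gompertz_hazard(
    mid_ages: np.ndarray, hazards: np.ndarray, weights: np.ndarray | None = None
) -> GompertzFit:
    """Weighted least-squares line through ln(hazard) vs age -> (a, g)."""
    mid_ages = np.asarray(mid_ages, float)
    hazards = np.asarray(hazards, float)
    keep = hazards > 0
    if keep.sum() < 3:
        raise ValueError("need at least 3 age bins with positive hazard")
    x = mid_ages[keep]
    y = np.log(hazards[keep])
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)[keep]
    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    g = (w * (x - xbar) * (y - ybar)).sum() / (w * (x - xbar) ** 2).sum()
    ln_a = ybar - g * xbar
    return GompertzFit(a=float(np.exp(ln_a)), g=float(g))


def fit_gompertz(sample: SurvivalSample, bin_width: float = 7.0) -> GompertzFit:
    """Fit the Gompertz hazard a*exp(g*t) from death times via a life table.

    Per-bin hazard is the actuarial rate ``-ln(1 - d/n) / bin_width`` (d
    deaths among n at risk entering the bin), which corrects for within-bin
    depletion; the log-hazard regression is weighted by deaths.
    """
    if not sample.fully_observed:
        raise ValueError("Gompertz fit expects an uncensored lifespan sample")
    mids, deaths, at_risk = _life_table(sample.death_times, bin_width)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(at_risk > 0, deaths / at_risk, 0.0)
        hazard = np.where(q < 1.0, -np.log1p(-q) / bin_width, np.nan)
    usable = (deaths > 0) & np.isfinite(hazard) & (hazard > 0)
    if usable.sum() < 3:
        raise ValueError("need at least 3 non-empty age bins for the Gompertz fit")
    return fit_gompertz_hazard(mids[usable], hazard[usable], weights=deaths[usable])


# ---------------------------------------------------------------------------
# two-sample tests


def logrank_test(a: SurvivalSample, b: SurvivalSample) -> TestResult:
    """Two-group log-rank test (1 df) with hypergeometric variance."""
    if a.n == 0 or b.n == 0:
        raise ValueError("both samples must be non-empty")
    if not (a.events.any() or b.events.any()):
        raise ValueError("no observed deaths in either group")
    from lifelines.statistics import logrank_test as _ll_logrank

    res = _ll_logrank(a.times, b.times, event_observed_A=a.events, event_observed_B=b.events)
    return TestResult(name="log-rank", statistic=float(res.test_statistic), p_value=float(res.p_value))


def ks_test_survival(a: SurvivalSample, b: SurvivalSample) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test on death times.

    Exact small-sample p when n*m <= 10^4, asymptotic otherwise.  Censored
    input is rejected: use the log-rank test for censored data.
    """
    if not (a.fully_observed and b.fully_observed):
        raise ValueError("KS test requires uncensored samples; use logrank_test")
    method = "exact" if a.n * b.n <= 10_000 else "asymp"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on ties in exact mode
        res = stats.ks_2samp(a.times, b.times, method=method)
    return TestResult(name="kolmogorov-smirnov", statistic=float(res.statistic), p_value=float(res.pvalue))


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test (point-probability method) on a 2x2 table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ValueError("table entries must be non-negative integers")
        arr = arr.astype(int)
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        name="fisher-exact",
        statistic=float(odds),
        p_value=float(p),
        table=pd.DataFrame(arr),
    )


def wang_allison_test(a: SurvivalSample, b: SurvivalSample, q: float = 0.9) -> TestResult:
    """Wang-Allison test for maximum-lifespan differences.

    The threshold is the ``q``-th percentile (default 90th, averaging
    convention) of the pooled lifespans; the 2x2 table cross-classifies group
    by (alive at/after threshold) vs (dead before threshold) and is evaluated
    with Fisher's exact test.
    """
    if a.n + b.n < 20:
        raise ValueError("Wang-Allison test needs a combined n of at least 20")
    pooled = np.concatenate([a.times, b.times])
    threshold = float(np.quantile(pooled, q, method="averaged_inverted_cdf"))
    table = np.array(
        [
            [(a.times >= threshold).sum(), (a.times < threshold).sum()],
            [(b.times >= threshold).sum(), (b.times < threshold).sum()],
        ],
        dtype=int,
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        log.warning("Wang-Allison table has an empty margin; p set to 1")
        return TestResult(
            name="wang-allison",
            statistic=np.nan,
            p_value=1.0,
            table=pd.DataFrame(table, index=[a.label or "A", b.label or "B"],
                               columns=["alive", "dead"]),
        )
    res = fisher_exact_2x2(table)
    return TestResult(
        name="wang-allison",
        statistic=res.statistic,
        p_value=res.p_value,
        table=pd.DataFrame(table, index=[a.label or "A", b.label or "B"],
                           columns=["alive", "dead"]),
    )


def relative_difference(control: float, experimental: float) -> float:
    """Percent difference 100*(experimental-control)/control, to one decimal."""
    if control == 0:
        raise ValueError("control value must be non-zero")
    return round(100.0 * (experimental - control) / control, 1)


def fecundity_ttest(group_a, group_b) -> TestResult:
    """Two-sample Student t (pooled variance), two-sided, per weekly time point."""
    x = np.asarray(group_a, float)
    y = np.asarray(group_b, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0 and x.mean() == y.mean():
        return TestResult(name="t-student", statistic=0.0, p_value=1.0)
    res = stats.ttest_ind(x, y, equal_var=True)
    return TestResult(name="t-student", statistic=float(res.statistic), p_value=float(res.pvalue))
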