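"""Standardized precipitation index and climate-NDVI context analysis.

SPI at scale k months: accumulate precipitation over rolling k-month
windows, fit a zero-inflated gamma distribution per calendar month
(windows ending in January are compared with other Januaries, etc.),
and transform each accumulation through the fitted CDF to a standard
normal quantile.  SPI 0 is the median for that month-of-year and scale;
+/-2 mark exceptionally wet/dry conditions.  Zero inflation uses the
mixed CDF H(x) = q + (1 - q) G(x) with q the no-rain probability and G
the gamma CDF fitted to the positive accumulations — necessary in arid
records where short-scale windows are often completely dry.

Also provided: categorical wet/dry/normal transition detection, the
per-scene standard deviation of NDVI across field samples, and a
permutation test for whether highly ranked classifier covariates
cluster just after climatic transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import SampleSet
from .stack import NDVIStack
from .synthetic import ClimateRecord

__all__ = [
    "SPISeries",
    "AlignmentResult",
    "aggregate_monthly",
    "spi",
    "categorize_spi",
    "detect_transitions",
    "ndvi_sd_series",
    "importance_transition_alignment",
    "SPI_CATEGORIES",
]

logger = logging.getLogger(__name__)

#: category thresholds: exceptional anchors at +/-2, moderate edges at +/-1
SPI_CATEGORIES = ["exceptionally dry", "dry", "normal", "wet", "exceptionally wet"]


def aggregate_monthly(daily: ClimateRecord) -> pd.Series:
    """Calendar-month precipitation totals (mm), PeriodIndex-ed.

    Partial months at either end of the record are dropped (logged) so
    every total covers a complete month.
    """
    if len(daily.dates) == 0:
        raise ValueError("empty climate record")
    s = pd.Series(daily.precip, index=daily.dates)
    monthly = s.resample("MS").sum()
    coverage = s.resample("MS").size()
    expected = monthly.index.days_in_month
    complete = coverage.values == expected
    if not complete.all():
        dropped = monthly.index[~complete].strftime("%Y-%m").tolist()
        logger.info("dropping partial months: %s", dropped)
    monthly = monthly[complete]
    monthly.index = monthly.index.to_period("M")
    monthly.name = "precip_mm"
    return monthly


@dataclass
class SPISeries:
    """Standardized precipitation values at one accumulation scale."""

    months: pd.PeriodIndex
    scale: int
    values: np.ndarray  # NaN where undefined
    categories: pd.Series  # label per defined month

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "month": self.months.strftime("%Y-%m"),
                "spi": self.values,
                "category": self.categories.values,
            }
        )


def categorize_spi(values) -> pd.Series:
    """Label SPI values (exceptionally dry <= -2 ... exceptionally wet >= 2)."""
    values = np.asarray(values, dtype=float)
    labels = np.full(values.shape, None, dtype=object)
    defined = np.isfinite(values)
    labels[defined] = "normal"
    labels[defined & (values <= -1.0)] = "dry"
    labels[defined & (values <= -2.0)] = "exceptionally dry"
    labels[defined & (values >= 1.0)] = "wet"
    labels[defined & (values >= 2.0)] = "exceptionally wet"
    return pd.Series(labels)


def _fit_gamma(x: np.ndarray) -> tuple[float, float]:
    """Gamma (shape, scale) for positive accumulations.

    Maximum likelihood with the location pinned at zero; falls back to
    Thom's approximation when the MLE does not converge.
    """
    try:
        shape, _, scale = stats.gamma.fit(x, floc=0)
        if np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0:
            return shape, scale
    except Exception:  # noqa: BLE001 - any optimizer failure falls through
        pass
    mean = x.mean()
    a_stat = np.log(mean) - np.mean(np.log(x))
    if a_stat <= 0:
        return 1.0, mean
    shape = (1.0 + np.sqrt(1.0 + 4.0 * a_stat / 3.0)) / (4.0 * a_stat)
    return shape, mean / shape


def spi(monthly: pd.Series, scale_months: int, min_windows: int = 30) -> SPISeries:
    """SPI of a monthly total series at one accumulation scale.

    The first (scale - 1) months are undefined (NaN).  A calendar month
    whose accumulations are all zero across the record has no wetness
    information and is flagged undefined too.
    """
    if not 1 <= scale_months <= 36:
        raise ValueError("scale must be between 1 and 36 months")
    monthly = monthly.sort_index()
    accum = monthly.rolling(scale_months).sum()
    valid = accum.dropna()
    if len(valid) < min_windows:
        raise ValueError(
            f"only {len(valid)} accumulation windows at scale {scale_months}; "
            f"need >= {min_windows} for a reliable distribution fit"
        )
    out = np.full(len(monthly), np.nan)
    months_of_year = monthly.index.month
    for moy in np.unique(months_of_year[scale_months - 1 :]):
        sel = (months_of_year == moy) & ~accum.isna().values
        x = accum.values[sel]
        q = float(np.mean(x == 0.0))
        pos = x[x > 0]
        if pos.size == 0:
            continue  # all-dry month of year: SPI undefined
        if pos.std() <= 1e-12 * pos.mean():
            # point mass: every identical accumulation sits at its median
            point = pos[0]
            gcdf = np.where(x < point, 0.0, np.where(x > point, 1.0, 0.5))
        else:
            shape, scale = _fit_gamma(pos)
            gcdf = stats.gamma.cdf(x, shape, scale=scale)
        cdf = q + (1.0 - q) * gcdf
        # keep probabilities strictly inside (0, 1) for the normal quantile
        eps = 1.0 / (2.0 * x.size)
        out[sel] = stats.norm.ppf(np.clip(cdf, eps, 1.0 - eps))
    return SPISeries(
        months=monthly.index,
        scale=scale_months,
        values=out,
        categories=categorize_spi(out),
    )


def detect_transitions(
    spi_series, dry_threshold: float = -1.0, wet_threshold: float = 1.0
) -> list:
    """Months where the coarse climatic state (dry/normal/wet) changes.

    Accepts one SPISeries or a list of them (short scales); the union of
    per-scale transition months is returned sorted.  A transition is a
    defined month whose band differs from the previous defined month's.
    """
    series_list = spi_series if isinstance(spi_series, (list, tuple)) else [spi_series]
    found = set()
    for s in series_list:
        band = np.full(len(s.values), None, dtype=object)
        band[np.asarray(s.values) <= dry_threshold] = "dry"
        band[np.asarray(s.values) >= wet_threshold] = "wet"
        defined = np.isfinite(np.asarray(s.values, dtype=float))
        band[defined & pd.isna(band)] = "normal"
        prev = None
        for i in np.nonzero(defined)[0]:
            if prev is not None and band[i] != prev:
                found.add(s.months[i])
            prev = band[i]
    return sorted(found)


def ndvi_sd_series(stack: NDVIStack, samples: SampleSet) -> pd.Series:
    """Per-scene population SD of NDVI over the sample pixels."""
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    rows = samples.frame["row"].to_numpy(dtype=int)
    cols = samples.frame["col"].to_numpy(dtype=int)
    values = stack.values[:, rows, cols]  # (T, n_samples)
    sd = np.std(values, axis=1)  # population SD (ddof=0)
    return pd.Series(sd, index=stack.dates, name="ndvi_sd")


@dataclass
class AlignmentResult:
    """Importance-vs-transition alignment statistic and permutation p."""

    statistic: float  # mean rank in post-transition windows minus elsewhere
    p_value: float
    n_post: int
    n_other: int
    n_permutations: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_post_transition_scenes": self.n_post,
            "n_other_scenes": self.n_other,
            "n_permutations": self.n_permutations,
        }


def importance_transition_alignment(
    importance: pd.Series,
    transitions,
    window_steps: int,
    n_permutations: int = 999,
    seed: int = 0,
) -> AlignmentResult:
    """Do important covariate scenes cluster just after SPI transitions?

    ``importance`` maps scene dates to importance ranks (1 = most
    important).  Scenes within ``window_steps`` grid steps at or after a
    transition month form the post-transition group; the statistic is
    their mean rank minus the mean rank of all other scenes, so negative
    values mean post-transition scenes are more important.  The one-sided
    p-value permutes ranks over scenes.
    """
    transitions = list(transitions)
    if not transitions:
        raise ValueError("no transitions supplied")
    if window_steps < 1:
        raise ValueError("window_steps must be >= 1")
    dates = pd.DatetimeIndex(importance.index)
    ranks = importance.to_numpy(dtype=float)
    t_stamps = [
        pd.Timestamp(t.start_time) if isinstance(t, pd.Period) else pd.Timestamp(t)
        for t in transitions
    ]
    post = np.zeros(len(dates), dtype=bool)
    for t in t_stamps:
        after = np.nonzero(dates >= t)[0]
        post[after[:window_steps]] = True
    n_post, n_other = int(post.sum()), int((~post).sum())
    if n_post == 0 or n_other == 0:
        return AlignmentResult(0.0, 1.0, n_post, n_other, 0)

    def stat(r):
        return float(r[post].mean() - r[~post].mean())

    observed = stat(ranks)
    rng = np.random.default_rng(seed)
    hits = 1  # add-one correction: the observed labelling counts
    for _ in range(n_permutations):
        if stat(rng.permutation(ranks)) <= observed:
            hits += 1
    return AlignmentResult(
        statistic=observed,
        p_value=hits / (n_permutations + 1),
        n_post=n_post,
        n_other=n_other,
        n_permutations=n_permutations,
    )
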