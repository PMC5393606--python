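"""Synthetic monsoon climate and NDVI scenes with known ground truth.

The generator emulates the structure a hyper-temporal classification
protocol assumes in a semi-arid rangeland: per-pixel NDVI is a smooth
seasonal cycle whose amplitude is set jointly by the soil-defined
ecological site class, the ecological state (degradation level), and
antecedent precipitation, observed through additive noise and QA gaps.

Model per pixel p with site class c and state s:

    NDVI_p(t) = b_c + A_c * m_s * S(doy(t)) * g(Pbar_tau(t)) + eps(t)

* ``S`` — truncated-cosine seasonal bump peaking at day-of-year 260
  (mid/late September, the C4-grass biomass peak) and zero in winter,
* ``m_s`` — state amplitude multiplier; grassland-reference classes lose
  amplitude as they degrade toward shrubland/bare (states 6-7), while
  savanna-reference classes gain amplitude from savanna (state 3) to
  shrub-dominated/shrubland (states 5-6),
* ``Pbar_tau`` — mean daily precipitation (mm/day) over the preceding
  ``tau`` days; ``g(x) = (1 - lam) + lam * x / (x + h)`` is a saturating
  moisture response with sensitivity ``lam`` and half-saturation ``h``,
* ``eps`` — i.i.d. Gaussian noise, clipped so values stay in [-1, 1].

Daily precipitation is zero-inflated: Bernoulli occurrence with the
probability concentrated in the 1 July - 1 October monsoon window and
gamma-distributed event amounts; multi-year wet/dry regimes scale the
amount distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import GeoTransform
from .stack import NDVIStack

__all__ = [
    "ClimateRecord",
    "ClassParams",
    "SceneConfig",
    "SceneTruth",
    "simulate_precipitation",
    "simulate_scene",
    "inject_gaps",
    "paper_like_classes",
    "paper_like_states",
    "paper_like_config",
    "block_layout",
    "draw_samples",
    "MONSOON_START_DOY",
    "MONSOON_END_DOY",
]

# summer monsoon window: 1 July - 1 October
MONSOON_START_DOY = 182
MONSOON_END_DOY = 274

SEASONAL_PEAK_DOY = 260


@dataclass
class ClimateRecord:
    """Daily precipitation record (mm), strictly increasing dates."""

    dates: pd.DatetimeIndex
    precip: np.ndarray

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        self.precip = np.asarray(self.precip, dtype=float)
        if len(self.dates) != self.precip.size:
            raise ValueError("dates and precip lengths differ")
        if len(self.dates) > 1 and not self.dates.is_monotonic_increasing:
            raise ValueError("dates must be increasing")
        if self.dates.has_duplicates:
            raise ValueError("duplicate dates")
        if (self.precip < 0).any():
            raise ValueError("negative precipitation")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates.strftime("%Y-%m-%d"), "precip_mm": self.precip})


@dataclass(frozen=True)
class ClassParams:
    """Phenology parameters of one ecological site class.

    base : background NDVI floor b_c
    amplitude : reference-state seasonal amplitude A_c
    tau_days : antecedent-moisture averaging window (days)
    lam : moisture sensitivity in [0, 1] (0 = climate-invariant)
    half_sat : half-saturation of the moisture response (mm/day)
    reference : 'grassland' or 'savanna' state-and-transition family
    """

    name: str
    base: float
    amplitude: float
    tau_days: int
    lam: float
    half_sat: float = 1.5
    reference: str = "grassland"


@dataclass
class SceneConfig:
    """Full specification of a synthetic scene.

    ``layout_class``/``layout_state`` assign every pixel exactly one
    (site class, state code); ``states`` maps each reference family to
    its per-state amplitude multipliers m_s.
    """

    n_rows: int
    n_cols: int
    classes: list  # list[ClassParams]
    states: dict  # {reference family: {state code: multiplier}}
    layout_class: np.ndarray  # (R, C) of class-name strings
    layout_state: np.ndarray  # (R, C) of int state codes 1..7
    noise_sd: float = 0.02
    missing_rate: float = 0.0
    seed: int = 0
    transform: GeoTransform = field(default_factory=lambda: GeoTransform.north_up(0.0, 0.0, 30.0))

    def __post_init__(self):
        self.layout_class = np.asarray(self.layout_class)
        self.layout_state = np.asarray(self.layout_state, dtype=int)
        if self.layout_class.shape != (self.n_rows, self.n_cols):
            raise ValueError("layout_class shape mismatch")
        if self.layout_state.shape != (self.n_rows, self.n_cols):
            raise ValueError("layout_state shape mismatch")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        known = {p.name for p in self.classes}
        found = set(np.unique(self.layout_class))
        if not found <= known:
            raise ValueError(f"unknown class labels in layout: {sorted(found - known)}")
        for p in self.classes:
            mult = self.states.get(p.reference, {})
            used = set(np.unique(self.layout_state[self.layout_class == p.name]))
            if not used <= set(mult):
                raise ValueError(
                    f"states {sorted(used - set(mult))} undefined for reference '{p.reference}'"
                )

    @property
    def class_names(self) -> list:
        return [p.name for p in self.classes]


@dataclass
class SceneTruth:
    """Per-pixel ground truth of a generated scene."""

    class_raster: np.ndarray
    state_raster: np.ndarray
    params: SceneConfig


def simulate_precipitation(start_date, end_date, regime_schedule, seed: int) -> ClimateRecord:
    """Daily monsoon-concentrated precipitation with multi-year regimes.

    Parameters
    ----------
    regime_schedule : list of (start, end, multiplier)
        Contiguous, non-overlapping date intervals (inclusive) covering
        [start_date, end_date]; the multiplier scales expected rainfall
        amounts (2.0 = twice the baseline expected monthly total).
    seed : RNG seed; identical inputs give identical records.

    Baseline: rain occurs on ~45% of monsoon days and ~8% of days
    outside the window, with gamma(shape 0.9, scale 4.4) event sizes
    (~250 mm/yr, roughly two-thirds of it inside the monsoon).
    """
    start = pd.Timestamp(start_date)
    end = pd.Timestamp(end_date)
    if end <= start:
        raise ValueError("end_date must be after start_date")
    if len(regime_schedule) == 0:
        raise ValueError("regime schedule is empty")
    intervals = [(pd.Timestamp(s), pd.Timestamp(e), float(m)) for s, e, m in regime_schedule]
    intervals.sort(key=lambda t: t[0])
    if intervals[0][0] > start or intervals[-1][1] < end:
        raise ValueError("regime schedule does not cover the record span")
    for (s0, e0, _), (s1, _, _) in zip(intervals, intervals[1:]):
        if s1 != e0 + pd.Timedelta(days=1):
            raise ValueError("regime intervals must be contiguous and non-overlapping")

    dates = pd.date_range(start, end, freq="D")
    mult = np.empty(len(dates))
    for s, e, m in intervals:
        mult[(dates >= s) & (dates <= e)] = m

    doy = dates.dayofyear.values
    in_monsoon = (doy >= MONSOON_START_DOY) & (doy < MONSOON_END_DOY)
    p_rain = np.where(in_monsoon, 0.45, 0.08)

    rng = np.random.default_rng(seed)
    occurs = rng.random(len(dates)) < p_rain
    amounts = rng.gamma(shape=0.9, scale=4.4, size=len(dates)) * mult
    precip = np.where(occurs, amounts, 0.0)
    return ClimateRecord(dates=dates, precip=precip)


def _antecedent_mean(climate: ClimateRecord, time_grid: pd.DatetimeIndex, tau_days: int) -> np.ndarray:
    """Mean daily precipitation over the tau days ending at each grid date."""
    # cumulative sum with a leading zero for O(1) window sums
    csum = np.concatenate([[0.0], np.cumsum(climate.precip)])
    out = np.empty(len(time_grid))
    for i, t in enumerate(time_grid):
        hi = np.searchsorted(climate.dates.values, np.datetime64(t), side="right")
        lo = np.searchsorted(
            climate.dates.values, np.datetime64(t - pd.Timedelta(days=tau_days)), side="right"
        )
        n = hi - lo
        out[i] = (csum[hi] - csum[lo]) / n if n > 0 else 0.0
    return out


def seasonal_curve(doy: np.ndarray) -> np.ndarray:
    """Truncated-cosine bump peaking at day-of-year 260, zero in winter."""
    phase = 2.0 * np.pi * (np.asarray(doy, dtype=float) - SEASONAL_PEAK_DOY) / 365.25
    return np.maximum(np.cos(phase), 0.0)


def simulate_scene(
    config: SceneConfig, climate: ClimateRecord, time_grid: pd.DatetimeIndex
) -> tuple[NDVIStack, SceneTruth]:
    """Generate an NDVI stack plus ground truth from a scene config.

    With ``noise_sd = 0`` two pixels sharing (class, state) have
    bit-identical series; output values are clipped to [-1, 1].
    """
    time_grid = pd.DatetimeIndex(time_grid)
    T, R, C = len(time_grid), config.n_rows, config.n_cols
    doy = time_grid.dayofyear.values
    season = seasonal_curve(doy)

    # deterministic (class, state) template series
    templates: dict[tuple[str, int], np.ndarray] = {}
    for p in config.classes:
        pbar = _antecedent_mean(climate, time_grid, p.tau_days)
        g = (1.0 - p.lam) + p.lam * pbar / (pbar + p.half_sat)
        for state, m in config.states[p.reference].items():
            templates[(p.name, state)] = p.base + p.amplitude * m * season * g

    values = np.empty((T, R, C))
    for r in range(R):
        for c in range(C):
            values[:, r, c] = templates[(config.layout_class[r, c], int(config.layout_state[r, c]))]

    rng = np.random.default_rng(config.seed)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=values.shape)
    values = np.clip(values, -1.0, 1.0)

    stack = NDVIStack(
        values=values,
        mask=np.zeros((T, R, C), dtype=bool),
        dates=time_grid,
        transform=config.transform,
    )
    if config.missing_rate > 0:
        stack = inject_gaps(stack, config.missing_rate, seed=int(rng.integers(2**31)))
    truth = SceneTruth(
        class_raster=config.layout_class.copy(),
        state_raster=config.layout_state.copy(),
        params=config,
    )
    return stack, truth


def inject_gaps(stack: NDVIStack, missing_rate: float, seed: int) -> NDVIStack:
    """Mask a random fraction of observations (QA/cloud-gap emulation)."""
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    out = stack.copy()
    if missing_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    new_gaps = rng.random(stack.shape) < missing_rate
    out.mask = stack.mask | new_gaps
    out.values[out.mask] = np.nan
    return out


# ---------------------------------------------------------------------------
# "paper-like" preset: five semi-arid ecological site classes
# ---------------------------------------------------------------------------

def paper_like_classes() -> list:
    """Five site classes with a shared NDVI floor and distinct phenology.

    A common base (0.13) means class identity is carried by the seasonal
    term only, so degraded low-amplitude states converge spectrally
    across classes — the mechanism behind degraded-state confusion.
    """
    return [
        # short-window, strongly responsive annual-grass phenology
        ClassParams("Clayey", base=0.13, amplitude=0.20, tau_days=15, lam=0.95),
        ClassParams("Loamy", base=0.13, amplitude=0.28, tau_days=45, lam=0.80),
        ClassParams("Sandy", base=0.13, amplitude=0.36, tau_days=75, lam=0.65),
        ClassParams("Shallow sandy", base=0.13, amplitude=0.44, tau_days=30, lam=0.50),
        # deep-rooted woody savanna: slow, buffered moisture response
        ClassParams("Deep sand", base=0.13, amplitude=0.30, tau_days=150, lam=0.50, reference="savanna"),
    ]


def paper_like_states() -> dict:
    """Amplitude multipliers m_s by reference family and state code.

    Grassland-reference classes lose amplitude toward states 6/7;
    savanna-reference classes gain amplitude from state 3 to 5/6.
    """
    return {
        "grassland": {1: 1.00, 2: 0.95, 3: 0.85, 4: 0.70, 5: 0.55, 6: 0.40, 7: 0.30},
        "savanna": {1: 0.55, 2: 0.55, 3: 0.55, 4: 0.70, 5: 0.90, 6: 1.00, 7: 1.00},
    }


def block_layout(n_rows: int, n_cols: int, classes: list, states_per_class: dict) -> tuple:
    """Vertical class bands, each split into horizontal state strips.

    ``states_per_class`` maps class name -> list of state codes; the
    class band is divided evenly (top to bottom) among its states.
    """
    layout_class = np.empty((n_rows, n_cols), dtype=object)
    layout_state = np.ones((n_rows, n_cols), dtype=int)
    names = [p.name for p in classes]
    edges = np.linspace(0, n_cols, len(names) + 1).astype(int)
    for name, c0, c1 in zip(names, edges[:-1], edges[1:]):
        layout_class[:, c0:c1] = name
        codes = states_per_class[name]
        redges = np.linspace(0, n_rows, len(codes) + 1).astype(int)
        for code, r0, r1 in zip(codes, redges[:-1], redges[1:]):
            layout_state[r0:r1, c0:c1] = code
    return layout_class, layout_state


def paper_like_config(
    n_rows: int = 64,
    n_cols: int = 64,
    layout: str = "reference",
    noise_sd: float = 0.02,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> SceneConfig:
    """Preset scene configuration for the five-class semi-arid mosaic.

    layout='reference' places every class in its reference state (1 for
    grassland-family classes, 3 for Deep sand) — the class-separability
    setting.  layout='state_mixture' spreads each class across its full
    state-and-transition sequence, reproducing degraded-state spectral
    convergence.
    """
    classes = paper_like_classes()
    if layout == "reference":
        states_per_class = {p.name: [1 if p.reference == "grassland" else 3] for p in classes}
    elif layout == "state_mixture":
        states_per_class = {
            p.name: ([1, 2, 4, 6, 7] if p.reference == "grassland" else [3, 4, 5, 6])
            for p in classes
        }
    else:
        raise ValueError("layout must be 'reference' or 'state_mixture'")
    layout_class, layout_state = block_layout(n_rows, n_cols, classes, states_per_class)
    return SceneConfig(
        n_rows=n_rows,
        n_cols=n_cols,
        classes=classes,
        states=paper_like_states(),
        layout_class=layout_class,
        layout_state=layout_state,
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        seed=seed,
    )


def draw_samples(truth: SceneTruth, n_per_class: int, seed: int) -> pd.DataFrame:
    """Random field-point sample from a scene's ground truth.

    Returns a samples table (id, x, y, es_class, state_code) with map
    coordinates at pixel centres, ``n_per_class`` pixels per class drawn
    without replacement, spread across that class's states.
    """
    rng = np.random.default_rng(seed)
    tfm = truth.params.transform
    rows_out = []
    for name in truth.params.class_names:
        rr, cc = np.nonzero(truth.class_raster == name)
        if rr.size == 0:
            continue
        take = min(n_per_class, rr.size)
        pick = rng.choice(rr.size, size=take, replace=False)
        for k in pick:
            r, c = int(rr[k]), int(cc[k])
            x, y = tfm.xy(r, c)
            rows_out.append(
                {
                    "id": f"{name[:2]}-{r:03d}-{c:03d}",
                    "x": float(x),
                    "y": float(y),
                    "es_class": name,
                    "state_code": int(truth.state_raster[r, c]),
                }
            )
    return pd.DataFrame(rows_out)
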