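"""Monthly aggregation, direct age standardization, smoothing, onset rule.

Events are aggregated to a complete month x 5-year-age-group grid, converted
to directly age-standardized rates per 100 000 using standard-population
weights renormalized over the analysis band, smoothed with a trailing
annual (12-month) moving average to remove seasonality, and log-transformed.
The effective intervention onset under trailing smoothing is the first month
whose entire window lies at or after the policy month.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from synthits.registry_io import (
    FIVE_YEAR_GROUPS,
    CauseDefinition,
    EventTable,
    PopulationTable,
    StandardPopulation,
    StudyConfig,
    age_to_group,
    groups_in_band,
    match_cause,
)


@dataclass
class MonthlyCounts:
    """Event counts on the full month x 5-year age-group grid.

    ``df`` is indexed by month (Period[M]) with one column per 5-year group;
    cells are non-negative integers with explicit zeros (no missing cells).
    """

    df: pd.DataFrame
    cause: str
    sex: str = "all"

    def __post_init__(self) -> None:
        if (self.df.values < 0).any():
            raise ValueError("negative counts")
        if self.df.isna().any().any():
            raise ValueError("missing cells in the monthly grid")

    def band_total(self, band: str) -> pd.Series:
        """Total monthly count over the analysis band."""
        return self.df[groups_in_band(band)].sum(axis=1)


@dataclass
class RateSeries:
    """A monthly series of (log) age-standardized rates per 100 000.

    ``values`` are natural logs of the (optionally smoothed) standardized
    rate. If smoothed, the series starts at the first month with a full
    trailing window; ``onset`` is the effective intervention onset month.
    """

    months: pd.PeriodIndex
    values: np.ndarray
    cause: str = ""
    band: str = ""
    sex: str = "all"
    smoothed: bool = False
    window: int = 1
    onset: pd.Period | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.months = pd.PeriodIndex(self.months, freq="M")
        if len(self.months) != len(self.values):
            raise ValueError("months and values differ in length")
        if len(self.months) > 1:
            steps = np.diff(self.months.asi8)
            if (steps != 1).any():
                raise ValueError("months must be consecutive with no gaps")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def eligible(self) -> bool:
        """Usable as a donor/treated series: every value finite."""
        return bool(np.isfinite(self.values).all())

    @property
    def label(self) -> str:
        return f"{self.cause},{self.band},{self.sex}"

    def pre_mask(self, onset: pd.Period | None = None) -> np.ndarray:
        onset = onset if onset is not None else self.onset
        if onset is None:
            raise ValueError("no onset month set")
        return np.asarray(self.months < onset)

    def with_values(self, values: np.ndarray) -> "RateSeries":
        return replace(self, values=np.asarray(values, dtype=float))

    def aligned_with(self, other: "RateSeries") -> bool:
        return len(self.months) == len(other.months) and bool(
            (self.months == other.months).all())


def aggregate_monthly(events: EventTable, cause: CauseDefinition,
                      config: StudyConfig, sex: str = "all") -> MonthlyCounts:
    """Aggregate daily events to monthly counts per 5-year age group.

    The output grid covers every month of the study window and every 5-year
    group, with explicit zeros. ``sex='all'`` sums both sexes before any
    rate is formed (rates are nonlinear in counts, so sexes are combined on
    the count scale). Composite causes are sums of their member causes.
    """
    df = events.df
    if sex != "all":
        df = df[df["sex"] == sex]
    if len(df):
        keep = df["icd10"].map(lambda c: match_cause(c, cause, config.causes))
        df = df[keep]
    months = config.months
    grid = pd.DataFrame(0, index=months, columns=list(FIVE_YEAR_GROUPS))
    if len(df):
        month = df["event_date"].dt.to_period("M")
        group = df["age_years"].map(age_to_group)
        tab = df.groupby([month, group])["count"].sum()
        for (m, g), n in tab.items():
            if m in grid.index:
                grid.loc[m, g] += int(n)
    grid.index.name = "month"
    return MonthlyCounts(grid, cause=cause.name, sex=sex)


def age_standardize(counts: MonthlyCounts, pop: PopulationTable,
                    std: StandardPopulation, band: str) -> pd.Series:
    """Directly age-standardized monthly rate per 100 000 for a band.

    rate(month) = sum_a w~_a * (count_a / pop_a) * 100000, with w~_a the
    standard weights renormalized over the band's 5-year groups and pop_a
    the population of that calendar year (held constant within the year).
    """
    groups = groups_in_band(band)
    weights = std.renormalized(groups)
    months = counts.df.index
    years = sorted({m.year for m in months})
    popmat = pd.DataFrame(
        {g: {y: pop.get(y, g, counts.sex) for y in years} for g in groups})
    if (popmat <= 0).any().any():
        raise ValueError("zero or missing population in a needed cell")
    year_idx = pd.Index([m.year for m in months])
    crude = counts.df[groups].to_numpy(dtype=float) / popmat.loc[year_idx, groups].to_numpy()
    rate = crude @ weights.loc[groups].to_numpy() * 100_000.0
    return pd.Series(rate, index=months, name="rate")


def log_and_smooth(rates: pd.Series, window: int = 12, *,
                   order: str = "rate", meta: dict | None = None) -> RateSeries:
    """Trailing moving average then natural log of a monthly rate series.

    The smoothed value at month m is the mean over [m-window+1, m]; the
    first window-1 months are dropped. ``order='rate'`` (default) averages
    on the rate scale and then takes logs; ``order='log'`` averages the log
    rates instead. With ``window=1`` this is simply the log of the raw
    series.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(rates) < window:
        raise ValueError("series shorter than the smoothing window")
    months = pd.PeriodIndex(rates.index, freq="M")
    vals = rates.to_numpy(dtype=float)
    if order == "rate":
        sm = pd.Series(vals).rolling(window).mean().to_numpy()[window - 1:]
        bad = sm <= 0
        if bad.any():
            m = months[window - 1:][bad][0]
            raise ValueError(f"nonpositive smoothed rate at {m}")
        out = np.log(sm)
    elif order == "log":
        if (vals <= 0).any():
            m = months[vals <= 0][0]
            raise ValueError(f"nonpositive rate at {m} (log-scale smoothing)")
        out = pd.Series(np.log(vals)).rolling(window).mean().to_numpy()[window - 1:]
    else:
        raise ValueError(f"unknown smoothing order {order!r}")
    meta = meta or {}
    return RateSeries(months=months[window - 1:], values=out,
                      smoothed=window > 1, window=window, **meta)


def onset_month(policy_month: pd.Period | str, window: int = 12) -> pd.Period:
    """Effective intervention onset under trailing smoothing.

    The first month whose trailing window of length ``window`` contains
    only months at or after the policy month: policy_month + (window - 1).
    With a 12-month window and a March-2013 enactment this is February
    2014, the first month whose whole trailing year is under the policy.
    """
    policy_month = pd.Period(policy_month, freq="M")
    if window < 1:
        raise ValueError("window must be >= 1")
    return policy_month + (window - 1)


def build_rate_series(events: EventTable, cause: CauseDefinition,
                      config: StudyConfig, pop: PopulationTable,
                      std: StandardPopulation, band: str, sex: str = "all",
                      order: str = "rate") -> RateSeries:
    """Full pipeline: events -> monthly counts -> standardized -> smoothed log."""
    counts = aggregate_monthly(events, cause, config, sex=sex)
    raw = age_standardize(counts, pop, std, band)
    series = log_and_smooth(raw, config.smoothing_window, order=order,
                            meta={"cause": cause.name, "band": band, "sex": sex})
    series.onset = onset_month(config.policy_month, config.smoothing_window)
    return series
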