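"""Synthetic registry and rate-series generators with known ground truth.

Emulates the statistical structure the analysis assumes: eleven years of
monthly log-rates (132 months) for one treated series and a donor pool of
~33 candidate series sharing latent factors, with per-series linear trends,
12-month sinusoidal seasonality, and AR(1) noise on the log scale. The
treated series is a sparse weighted combination of donors plus an injected
intervention effect (a level shift and a slope change from a configurable
onset month), so every pipeline stage can be checked against ground truth.
A companion generator draws Poisson event counts whose expected
age-standardized rate equals a configured target, to exercise the
event-to-rate stages end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from synthits.rates import RateSeries
from synthits.registry_io import EventTable, PopulationTable, parse_band
from synthits.synthetic_control import DonorPool


@dataclass
class SimulationSpec:
    """Generative parameters for the rate-series simulator.

    Defaults mirror the study design: 132 months (2007-2017), a policy
    month of March 2013 (index 74), a 12-month trailing window so the
    effective onset is February 2014 (index 85), and a donor pool of 33
    candidate series. ``effect_level``/``effect_trend`` are the true values
    of the level (b6) and trend (b7) effects injected into the treated
    series from the onset month. Noise is AR(1) on the log scale.
    """

    n_months: int = 132
    start: str = "2007-01"
    n_donors: int = 33
    policy_index: int = 74
    window: int = 12
    effect_level: float = 0.0
    effect_trend: float = 0.0
    treated_weights: tuple[tuple[int, float], ...] = ((0, 0.5), (1, 0.3), (2, 0.2))
    treated_shift: float = 0.0
    phi: float = 0.3
    sigma: float = 0.05
    treated_sigma: float | None = None
    seasonal_amplitude: float = 0.05
    n_factors: int = 2
    factor_scale: float = 0.5
    donor_intercept_range: tuple[float, float] = (0.5, 4.0)
    donor_trend_range: tuple[float, float] = (-0.006, 0.006)
    event_target_rates: Mapping[str, float] | None = None
    event_icd10: str = "I21"
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.phi) < 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        if self.sigma < 0 or (self.treated_sigma is not None and self.treated_sigma < 0):
            raise ValueError("noise sigma must be >= 0")
        if not 0 <= self.policy_index < self.n_months:
            raise ValueError("policy_index outside the simulated window")
        if self.onset_index >= self.n_months:
            raise ValueError("onset (policy_index + window - 1) beyond the window")
        for j, w in self.treated_weights:
            if not (0 <= j < self.n_donors and np.isfinite(w)):
                raise ValueError("treated_weights must reference donors with finite weights")
        if self.event_target_rates is not None:
            if any(r < 0 for r in self.event_target_rates.values()):
                raise ValueError("negative target rate")

    @property
    def onset_index(self) -> int:
        """First month whose full trailing window is post-policy."""
        return self.policy_index + self.window - 1

    @property
    def months(self) -> pd.PeriodIndex:
        return pd.period_range(self.start, periods=self.n_months, freq="M")

    @property
    def onset(self) -> pd.Period:
        return self.months[self.onset_index]


@dataclass
class GroundTruth:
    """Noiseless components and true effects behind one simulated draw."""

    months: pd.PeriodIndex
    treated_noiseless: np.ndarray      # structural treated incl. the injected effect
    counterfactual_noiseless: np.ndarray
    effect_path: np.ndarray            # effect_level + effect_trend * months-since-onset
    weights: dict[int, float]
    donor_structural: np.ndarray       # (n_months, n_donors) noiseless donors


def _ar1(rng: np.random.Generator, n: int, phi: float, sigma: float) -> np.ndarray:
    if sigma == 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sigma, n)
    x = np.empty(n)
    x[0] = innov[0] / np.sqrt(1 - phi**2)   # stationary start
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t]
    return x


def simulate_series(spec: SimulationSpec,
                    rng: np.random.Generator | None = None
                    ) -> tuple[RateSeries, DonorPool, GroundTruth]:
    """Draw a treated series, its donor pool, and the ground truth.

    Donors: intercept + linear trend + 12-month sinusoid + loadings on
    shared latent factors + AR(1) noise. Treated: sparse weighted
    combination of the OBSERVED donors (so with zero noise it is an exact
    linear combination) plus the injected level/trend effect and its own
    AR(1) noise. Deterministic given the spec's seed.
    """
    rng = rng or np.random.default_rng(spec.seed)
    n, p = spec.n_months, spec.n_donors
    t = np.arange(n, dtype=float)
    months = spec.months

    factors = np.zeros((spec.n_factors, n))
    for k in range(spec.n_factors):
        rw = np.cumsum(rng.normal(0.0, 1.0, n))
        sd = rw.std()
        factors[k] = spec.factor_scale * (rw - rw.mean()) / (sd if sd > 0 else 1.0)

    lo, hi = spec.donor_intercept_range
    intercepts = rng.uniform(lo, hi, p)
    trends = rng.uniform(*spec.donor_trend_range, p)
    amps = rng.uniform(0.0, spec.seasonal_amplitude, p) if spec.seasonal_amplitude else np.zeros(p)
    phases = rng.uniform(0, 12, p)
    loadings = rng.normal(0.0, 1.0, (p, spec.n_factors))

    structural = np.empty((n, p))
    for j in range(p):
        structural[:, j] = (
            intercepts[j] + trends[j] * t
            + amps[j] * np.sin(2 * np.pi * (t + phases[j]) / 12.0)
            + loadings[j] @ factors
        )
    noise = np.column_stack([_ar1(rng, n, spec.phi, spec.sigma) for _ in range(p)])
    observed = structural + noise

    donors = [
        RateSeries(months=months, values=observed[:, j], cause=f"donor_{j:02d}",
                   band="20+", sex="all", smoothed=True, window=spec.window,
                   onset=spec.onset)
        for j in range(p)
    ]
    pool = DonorPool(donors, [d.label for d in donors])

    weights = dict(spec.treated_weights)
    w = np.zeros(p)
    for j, wt in weights.items():
        w[j] = wt
    post = t >= spec.onset_index
    effect = np.where(post,
                      spec.effect_level + spec.effect_trend * (t - spec.onset_index),
                      0.0)
    tr_sigma = spec.sigma if spec.treated_sigma is None else spec.treated_sigma
    base = observed @ w + spec.treated_shift
    treated_vals = base + effect + _ar1(rng, n, spec.phi, tr_sigma)
    treated = RateSeries(months=months, values=treated_vals, cause="treated",
                         band="20+", sex="all", smoothed=True,
                         window=spec.window, onset=spec.onset)

    truth = GroundTruth(
        months=months,
        treated_noiseless=structural @ w + spec.treated_shift + effect,
        counterfactual_noiseless=structural @ w + spec.treated_shift,
        effect_path=effect,
        weights=weights,
        donor_structural=structural,
    )
    return treated, pool, truth


def simulate_itsa_panel(true_beta: np.ndarray, n_months: int = 121,
                        onset_index: int = 74, phi: float = 0.3,
                        sigma: float = 0.05, start: str = "2007-12",
                        centering: bool = True,
                        rng: np.random.Generator | None = None,
                        seed: int | None = None
                        ) -> tuple[RateSeries, RateSeries]:
    """Treated/control pair drawn directly from the 8-coefficient model.

    Generates both series from the segmented-regression equation with
    independent AR(1) errors, using the same interaction-centering
    convention as the fitting code, so the true coefficient vector is the
    estimand. ``onset_index`` is the 0-based position of the onset month.
    """
    true_beta = np.asarray(true_beta, dtype=float)
    if true_beta.shape != (8,):
        raise ValueError("true_beta must have 8 entries")
    rng = rng if rng is not None else np.random.default_rng(seed)
    months = pd.period_range(start, periods=n_months, freq="M")
    t = np.arange(1, n_months + 1, dtype=float)
    X = (np.arange(n_months) >= onset_index).astype(float)
    Tpost = (t - t[onset_index]) if centering else t
    XT = X * Tpost
    b = true_beta

    def series_mean(z: float) -> np.ndarray:
        return (b[0] + b[1] * t + b[2] * X + b[3] * XT
                + z * (b[4] + b[5] * t + b[6] * X + b[7] * XT))

    onset = months[onset_index]
    treated = RateSeries(months=months,
                         values=series_mean(1.0) + _ar1(rng, n_months, phi, sigma),
                         cause="treated", onset=onset)
    control = RateSeries(months=months,
                         values=series_mean(0.0) + _ar1(rng, n_months, phi, sigma),
                         cause="control", onset=onset)
    return treated, control


def simulate_events(spec: SimulationSpec, pop: PopulationTable,
                    rng: np.random.Generator | None = None) -> EventTable:
    """Poisson event counts matching the spec's target age-specific rates.

    For every month, 5-year group and sex in the population table, the
    count is Poisson with mean target_rate * population / 100 000. The
    expected directly standardized rate therefore equals the weighted
    target. Rows carry the group's lower age bound and the spec's ICD-10
    code; zero-count cells emit no rows.
    """
    if spec.event_target_rates is None:
        raise ValueError("spec.event_target_rates is not set")
    rng = rng or np.random.default_rng(spec.seed)
    sexes = sorted(pop.df["sex"].unique())
    rows = []
    for month in spec.months:
        for group, rate in spec.event_target_rates.items():
            low, _ = parse_band(group)
            for sex in sexes:
                mean = rate * pop.get(month.year, group, sex) / 100_000.0
                count = int(rng.poisson(mean))
                if count > 0:
                    rows.append({
                        "event_date": month.to_timestamp(how="start"),
                        "icd10": spec.event_icd10,
                        "age_years": low,
                        "sex": sex,
                        "count": count,
                    })
    df = pd.DataFrame(rows, columns=["event_date", "icd10", "age_years", "sex", "count"])
    if df.empty:
        df["count"] = df["count"].astype(int)
    return EventTable(df)
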