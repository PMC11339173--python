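"""Effect-size conversions and counterfactual averted-event accounting.

The segmented-regression coefficients live on the log-rate scale. Reported
effects use the convention percent = 100 * beta (a first-order reading of a
log-point change; the exact transform 100 * (e^beta - 1) is carried
alongside, labeled), and absolute = reference_rate * beta in events per
100 000, with the reference rate's provenance (pre- or post-intervention
mean) recorded. Averted events compare observed counts with the
counterfactual implied by the synthetic control through a rate-ratio
scaling of the observed counts, which avoids inverting a standardized rate
back to crude counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from synthits.itsa import ItsaFit
from synthits.rates import RateSeries


def percent_change(beta: float) -> float:
    """Level/trend coefficient as a percent: 100 * beta."""
    return 100.0 * beta


def percent_change_exact(beta: float) -> float:
    """Exact log-to-ratio percent change: 100 * (e^beta - 1)."""
    return 100.0 * float(np.expm1(beta))


def absolute_change(beta: float, reference_rate: float) -> float:
    """Absolute effect in events per 100 000: reference_rate * beta.

    ``reference_rate`` is a summary rate (events per 100 000) whose
    provenance (pre- or post-intervention mean) the caller records; it must
    be positive. Reported tables round to 2 decimals.
    """
    if reference_rate <= 0:
        raise ValueError("reference_rate must be positive")
    return reference_rate * beta


@dataclass
class EffectSummary:
    """One coefficient's effect on every reporting scale."""

    name: str
    beta: float
    p_one_tail: float
    p_two_tail: float
    percent: float = field(init=False)
    percent_exact: float = field(init=False)
    reference_rate: float | None = None
    reference_kind: str = "post_mean"   # provenance of the reference rate
    absolute: float | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        self.percent = percent_change(self.beta)
        self.percent_exact = percent_change_exact(self.beta)
        if self.reference_rate is not None:
            self.absolute = absolute_change(self.beta, self.reference_rate)


@dataclass
class AvertedEvents:
    """Observed vs counterfactual event counts over the post-onset window."""

    actual_events: float
    counterfactual_events: float

    @property
    def averted(self) -> float:
        return self.counterfactual_events - self.actual_events

    @property
    def percent_averted(self) -> float:
        if self.counterfactual_events <= 0:
            raise ValueError("percent_averted undefined for nonpositive counterfactual")
        return 100.0 * self.averted / self.counterfactual_events


def averted_events(actual: pd.Series, treated: RateSeries,
                   synthetic: RateSeries,
                   onset: pd.Period | None = None) -> AvertedEvents:
    """Counterfactual averted events over the post-onset months.

    ``actual`` holds observed monthly event counts indexed by month. The
    monthly counterfactual count is actual * exp(synthetic - treated) on
    the log-rate scale (rate-ratio scaling), summed over post-onset months.
    """
    if not treated.aligned_with(synthetic):
        raise ValueError("treated and synthetic series are not aligned")
    onset = pd.Period(onset, freq="M") if onset is not None else treated.onset
    if onset is None:
        raise ValueError("no onset month given")
    post = np.asarray(treated.months >= onset)
    if not post.any():
        raise ValueError("post-onset window is empty")
    months = treated.months[post]
    actual = actual.copy()
    actual.index = pd.PeriodIndex(actual.index, freq="M")
    missing = [m for m in months if m not in actual.index]
    if missing:
        raise ValueError(f"actual counts missing for months: {missing[:3]}...")
    a = actual.loc[months].to_numpy(dtype=float)
    ratio = np.exp(synthetic.values[post] - treated.values[post])
    counterfactual = float(np.sum(a * ratio))
    return AvertedEvents(actual_events=float(a.sum()),
                         counterfactual_events=counterfactual)


def significance_stars(p: float) -> str:
    """Reporting convention: p<.01 '***', p<.05 '**', p<.1 '*'."""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def report(entries: list[dict]) -> pd.DataFrame:
    """Results table shaped cause x band x {level, trend}.

    Each entry is a dict with keys ``cause``, ``band``, ``fit`` (ItsaFit)
    and optionally ``reference_rate`` / ``reference_kind`` and ``averted``
    (AvertedEvents). Returns a tidy DataFrame with one row per effect
    (level and trend), including confidence intervals and significance
    stars; write it with ``to_csv``/``to_json`` as needed.
    """
    if not entries:
        raise ValueError("no fitted effects to report")
    rows = []
    for entry in entries:
        fit: ItsaFit = entry["fit"]
        ref = entry.get("reference_rate")
        kind = entry.get("reference_kind", "post_mean")
        ci = fit.conf_int()
        for effect, coef_name in (("level", "b6_effect_level"),
                                  ("trend", "b7_effect_trend")):
            i = fit.names.index(coef_name)
            summ = EffectSummary(name=coef_name, beta=float(fit.beta[i]),
                                 p_one_tail=float(fit.p_one_tail[i]),
                                 p_two_tail=float(fit.p_two_tail[i]),
                                 reference_rate=ref, reference_kind=kind)
            row = {
                "cause": entry.get("cause", ""),
                "band": entry.get("band", ""),
                "effect": effect,
                "coefficient": summ.beta,
                "ci_low": float(ci[i, 0]),
                "ci_high": float(ci[i, 1]),
                "p_one_tail": summ.p_one_tail,
                "p_two_tail": summ.p_two_tail,
                "stars": significance_stars(summ.p_one_tail),
                "percent": summ.percent,
                "percent_exact": summ.percent_exact,
            }
            if summ.absolute is not None:
                row["absolute_per_100k"] = round(summ.absolute, 2)
                row["reference_kind"] = kind
            av = entry.get("averted")
            if av is not None and effect == "trend":
                row["averted_events"] = av.averted
                row["percent_averted"] = av.percent_averted
            rows.append(row)
    return pd.DataFrame(rows)
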