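"""Synthetic control groups by lasso (SCUL) with placebo inference.

A counterfactual for the treated log-rate series is built as an L1-penalized
regression on a donor pool of series from causes unrelated to the exposure,
fitted on pre-intervention months only. Weights may take any sign and an
unpenalized intercept is included — the lasso variant of the synthetic
control method, not the convex-hull-weight variant. The penalty is chosen by
rolling-origin cross-validation inside the pre-period; donor standardization
statistics are computed on the pre-period and frozen before the post-period
prediction. Inference uses in-space placebos ranked by post/pre RMSPE ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from synthits._lasso import lasso_cd, lasso_path
from synthits.rates import RateSeries
from synthits.registry_io import CauseDefinition

logger = logging.getLogger(__name__)


@dataclass
class DonorPool:
    """Aligned candidate control series with their cause/band/sex labels."""

    series: list[RateSeries]
    ids: list[str]
    rejected: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.series) != len(self.ids):
            raise ValueError("series and ids differ in length")

    def __len__(self) -> int:
        return len(self.series)

    @property
    def months(self) -> pd.PeriodIndex:
        return self.series[0].months

    def matrix(self) -> np.ndarray:
        """Donor values as an (n_months, n_donors) array."""
        return np.column_stack([s.values for s in self.series])

    def drop(self, index: int) -> "DonorPool":
        keep = [i for i in range(len(self.series)) if i != index]
        return DonorPool([self.series[i] for i in keep],
                         [self.ids[i] for i in keep])


@dataclass
class CVSpec:
    """Rolling-origin cross-validation settings for the penalty choice.

    The pre-period is split into consecutive validation blocks of length
    ceil(val_frac * n_pre), the last block ending at the last pre-period
    month; each fold trains on everything before its block. lambda is the
    grid value minimizing mean validation MSE (ties broken toward the
    largest, i.e. sparsest); ``one_se`` picks the largest lambda within one
    standard error of that minimum instead.
    """

    val_frac: float = 0.25
    n_folds: int = 3
    min_train: int = 12
    n_lambdas: int = 20
    lambda_min_ratio: float = 1e-3
    include_zero: bool = True
    one_se: bool = False
    tol: float = 1e-7


@dataclass
class SyntheticControlFit:
    """A fitted synthetic control and its pre/post diagnostics."""

    weights: np.ndarray          # per-donor coefficients on the standardized scale
    intercept: float
    lam: float
    donor_ids: list[str]
    fitted: RateSeries
    pre_rmspe: float
    post_rmspe: float
    standardized_fit: float      # pre-period RMSPE in treated pre-period SDs
    adequate: bool
    donor_scale: np.ndarray | None = None   # frozen pre-period donor SDs
    cv_table: pd.DataFrame | None = None

    @property
    def n_nonzero(self) -> int:
        return int(np.sum(self.weights != 0))

    @property
    def weights_natural(self) -> np.ndarray:
        """Weights on the donors' original (log-rate) scale."""
        if self.donor_scale is None:
            raise ValueError("donor scale not recorded")
        return self.weights / self.donor_scale

    @property
    def rmspe_ratio(self) -> float:
        return self.post_rmspe / self.pre_rmspe


@dataclass
class PlaceboResult:
    """Post/pre RMSPE ratios for the treated series and in-space placebos."""

    treated_ratio: float
    placebo_ratios: pd.Series
    n_filtered: int

    @property
    def rank_p(self) -> float:
        n = len(self.placebo_ratios)
        return (1 + int((self.placebo_ratios >= self.treated_ratio).sum())) / (1 + n)


def build_donor_pool(all_series: Sequence[RateSeries], treated: RateSeries,
                     exclusions: Sequence[str] = (),
                     causes: Mapping[str, CauseDefinition] | None = None) -> DonorPool:
    """Assemble the donor pool, excluding ineligible and related series.

    Excluded with a named reason: the treated cause itself; any composite
    cause containing it (when ``causes`` supplies definitions); causes on
    the exclusion list (tobacco-related or policy-covered conditions);
    series not aligned to the treated month grid; series flagged ineligible
    (non-finite values, e.g. a full window of zero counts).
    """
    exclusions = set(exclusions)
    composites = set()
    if causes:
        for c in causes.values():
            if treated.cause and treated.cause in c.composite_of:
                composites.add(c.name)
    donors, ids, rejected = [], [], {}
    for s in all_series:
        if s.cause == treated.cause and s.band == treated.band and s.sex == treated.sex:
            rejected[s.label] = "treated series itself"
        elif s.cause == treated.cause:
            rejected[s.label] = "same cause as treated"
        elif s.cause in composites:
            rejected[s.label] = f"composite containing {treated.cause!r}"
        elif s.cause in exclusions:
            rejected[s.label] = "on the exclusion list"
        elif not s.aligned_with(treated):
            rejected[s.label] = "months not aligned with treated series"
        elif not s.eligible:
            rejected[s.label] = "ineligible series (non-finite values)"
        else:
            donors.append(s)
            ids.append(s.label)
    for label, why in rejected.items():
        logger.info("donor %s rejected: %s", label, why)
    if not donors:
        raise ValueError("empty donor pool after exclusions")
    return DonorPool(donors, ids, rejected)


def _lambda_grid(Xc: np.ndarray, yc: np.ndarray, cv: CVSpec) -> np.ndarray:
    n = len(yc)
    lam_max = float(np.max(np.abs(Xc.T @ yc))) / n
    if lam_max <= 0:
        lam_max = 1.0
    grid = np.geomspace(lam_max, lam_max * cv.lambda_min_ratio, cv.n_lambdas)
    if cv.include_zero:
        grid = np.append(grid, 0.0)
    return grid


def _center(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    xm = X.mean(axis=0)
    ym = float(y.mean())
    return X - xm, y - ym, xm, ym


def fit_scul(treated: RateSeries, pool: DonorPool,
             onset: pd.Period | None = None, cv: CVSpec | None = None,
             lam: float | None = None,
             adequacy_threshold: float = 0.25) -> SyntheticControlFit:
    """Fit the lasso synthetic control on pre-onset months.

    Donors are standardized to zero mean / unit variance on the pre-period
    (statistics frozen for post-period prediction); the intercept is
    unpenalized. With ``lam=None`` the penalty is chosen by rolling-origin
    cross-validation within the pre-period; pass ``lam`` to fix it. The
    returned fit covers the full month range with the frozen weights.
    """
    cv = cv or CVSpec()
    onset = pd.Period(onset, freq="M") if onset is not None else treated.onset
    if onset is None:
        raise ValueError("no onset month given")
    if len(pool) < 2:
        raise ValueError("need at least 2 donors")
    for s in pool.series:
        if not s.aligned_with(treated):
            raise ValueError("donor months not aligned with treated series")

    pre = treated.pre_mask(onset)
    n_pre = int(pre.sum())
    if n_pre < 24:
        raise ValueError(f"only {n_pre} pre-onset months; need >= 24")

    y = treated.values
    sd_y = float(np.std(y[pre]))
    if sd_y <= 0:
        raise ValueError("treated series has zero pre-period variance")

    D = pool.matrix()
    mu = D[pre].mean(axis=0)
    sd = D[pre].std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Z = (D - mu) / sd_safe                      # frozen pre-period standardization
    Z[:, sd == 0] = 0.0                         # constant donors carry no signal

    Zpre, ypre = Z[pre], y[pre]

    cv_table = None
    if lam is None:
        Xc, yc, _, _ = _center(Zpre, ypre)
        grid = _lambda_grid(Xc, yc, cv)
        v = int(np.ceil(cv.val_frac * n_pre))
        folds = []
        end = n_pre
        for _ in range(cv.n_folds):
            start = end - v
            if start < cv.min_train:
                break
            folds.append((start, end))
            end = start
        if not folds:
            raise ValueError("pre-period too short for the cross-validation spec")
        errs = np.zeros((len(folds), len(grid)))
        for f, (start, end) in enumerate(folds):
            Xtr, ytr = Zpre[:start], ypre[:start]
            Xva, yva = Zpre[start:end], ypre[start:end]
            Xtrc, ytrc, xm, ym = _center(Xtr, ytr)
            betas = lasso_path(Xtrc, ytrc, grid, tol=cv.tol)
            for i, b in enumerate(betas):
                pred = (Xva - xm) @ b + ym
                errs[f, i] = float(np.mean((yva - pred) ** 2))
        mean_err = errs.mean(axis=0)
        best = int(np.argmin(mean_err))          # grid descends: first min = largest lam
        if cv.one_se:
            se = errs.std(axis=0, ddof=1) / np.sqrt(len(folds)) if len(folds) > 1 else 0 * mean_err
            ok = mean_err <= mean_err[best] + se[best]
            best = int(np.argmax(ok))
        lam = float(grid[best])
        cv_table = pd.DataFrame({"lam": grid, "mean_val_mse": mean_err})

    Xc, yc, xm, ym = _center(Zpre, ypre)
    beta = lasso_cd(Xc, yc, lam, tol=cv.tol)
    intercept = ym - float(xm @ beta)
    fitted_vals = Z @ beta + intercept

    fitted = RateSeries(months=treated.months, values=fitted_vals,
                        cause=f"synthetic({treated.cause})", band=treated.band,
                        sex=treated.sex, smoothed=treated.smoothed,
                        window=treated.window, onset=onset)
    resid = y - fitted_vals
    pre_rmspe = float(np.sqrt(np.mean(resid[pre] ** 2)))
    post_rmspe = float(np.sqrt(np.mean(resid[~pre] ** 2)))
    standardized = pre_rmspe / sd_y
    return SyntheticControlFit(
        weights=beta, intercept=intercept, lam=float(lam),
        donor_ids=list(pool.ids), fitted=fitted,
        pre_rmspe=pre_rmspe, post_rmspe=post_rmspe,
        standardized_fit=standardized,
        adequate=standardized <= adequacy_threshold,
        donor_scale=sd_safe,
        cv_table=cv_table,
    )


def assess_adequacy(fit: SyntheticControlFit, threshold: float = 0.25,
                    balance=None) -> bool:
    """Gate a fitted control: good pre-period fit and pre-period balance.

    Adequate iff the pre-period RMSPE is at most ``threshold`` treated
    pre-period standard deviations AND, when a :class:`~synthits.itsa.
    BalanceReport` is supplied, the pre-period level/trend differences
    (beta4, beta5) are jointly nonsignificant. Inadequate fits are reported,
    never silently dropped.
    """
    ok = fit.standardized_fit <= threshold
    if balance is not None:
        ok = ok and bool(balance.balanced)
    return bool(ok)


def placebo_test(pool: DonorPool, treated: RateSeries,
                 onset: pd.Period | None = None, cv: CVSpec | None = None,
                 adequacy_threshold: float = 0.25) -> PlaceboResult:
    """In-space placebo inference on the post/pre RMSPE ratio.

    Each donor is refit as pseudo-treated against the remaining donors;
    placebos whose pre-period fit fails the adequacy filter are excluded
    with a logged count. rank_p = (1 + #placebos with ratio >= treated) /
    (1 + #placebos).
    """
    if len(pool) < 2:
        raise ValueError("need at least 2 donors for placebo tests")
    fit_t = fit_scul(treated, pool, onset, cv, adequacy_threshold=adequacy_threshold)
    ratios, filtered = {}, 0
    for j, donor in enumerate(pool.series):
        rest = pool.drop(j)
        fit_j = fit_scul(donor, rest, onset, cv, adequacy_threshold=adequacy_threshold)
        if fit_j.standardized_fit > adequacy_threshold:
            filtered += 1
            continue
        ratios[pool.ids[j]] = fit_j.rmspe_ratio
    if filtered:
        logger.info("placebo test: %d placebos filtered for poor pre-period fit",
                    filtered)
    if not ratios:
        raise ValueError("all placebos filtered by the adequacy pre-fit rule")
    return PlaceboResult(treated_ratio=fit_t.rmspe_ratio,
                         placebo_ratios=pd.Series(ratios), n_filtered=filtered)
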