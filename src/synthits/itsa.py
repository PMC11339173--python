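"""Two-group interrupted time series with Newey-West (HAC) inference.

The model for a treated and a comparison log-rate series stacked into one
regression is

    Y_t = b0 + b1*T + b2*X + b3*X*T' + b4*Z + b5*Z*T + b6*Z*X + b7*Z*X*T' + e_t

with T the within-series month index, X the post-onset indicator, Z the
treated-group indicator, and T' either T itself or months-since-onset
(default: re-centered at the onset, so b6 is the level change AT the onset
and b7 the change in slope). b4/b5 measure pre-period balance between the
groups; b6/b7 are the causal level and trend effects. OLS point estimates
are combined with a Bartlett-kernel HAC covariance whose lag terms never
cross the boundary between the two stacked series, and one-tailed tests
(default direction: rates declined) alongside two-tailed ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from synthits.rates import RateSeries

COEF_NAMES = ("b0", "b1_trend", "b2_level_post", "b3_trend_post",
              "b4_group", "b5_group_trend", "b6_effect_level", "b7_effect_trend")

N_PARAMS = 8
_DF_ADJUST = 9  # residual df = n_obs - 9 (model parameter accounting)


@dataclass
class ItsaDesign:
    """Stacked design matrix for the two-group segmented regression."""

    X: np.ndarray                 # (2n, 8) regressors, column order COEF_NAMES
    y: np.ndarray                 # stacked outcomes, treated block first
    blocks: tuple[slice, slice]   # (treated rows, control rows)
    months: pd.PeriodIndex
    onset: pd.Period
    onset_index: int              # 0-based position of onset within a series
    centering: bool

    @property
    def n_obs(self) -> int:
        return len(self.y)

    def single_group(self) -> "ItsaDesign":
        """The control-block-only design (columns with Z are dropped)."""
        ctrl = self.blocks[1]
        return ItsaDesign(X=self.X[ctrl, :4], y=self.y[ctrl],
                          blocks=(slice(0, 0), slice(0, self.X[ctrl].shape[0])),
                          months=self.months, onset=self.onset,
                          onset_index=self.onset_index, centering=self.centering)


@dataclass
class ItsaFit:
    """OLS estimates with HAC covariance and one/two-tailed p-values."""

    beta: np.ndarray
    hac_cov: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p_one_tail: np.ndarray
    p_two_tail: np.ndarray
    lag: int
    residuals: np.ndarray
    n_obs: int
    names: tuple[str, ...] = COEF_NAMES

    @property
    def df_resid(self) -> int:
        return self.n_obs - _DF_ADJUST

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        q = stats.t.ppf(0.5 + level / 2, self.df_resid)
        return np.column_stack([self.beta - q * self.se, self.beta + q * self.se])


@dataclass
class BalanceReport:
    """Pre-period comparability of the treated and control series."""

    beta4: float
    beta5: float
    p4: float
    p5: float
    alpha: float
    balanced: bool


def build_design(treated: RateSeries, control: RateSeries,
                 onset: pd.Period | None = None,
                 centering: bool = True) -> ItsaDesign:
    """Stack the treated and control series into the 8-regressor design.

    Requires identical month grids and an onset strictly inside them. With
    ``centering`` (default) the time index in the post-onset interactions
    is replaced by months-since-onset, so the level-change coefficients
    measure the jump at the onset itself.
    """
    if not treated.aligned_with(control):
        raise ValueError("treated and control month grids are not aligned")
    onset = pd.Period(onset, freq="M") if onset is not None else treated.onset
    if onset is None:
        raise ValueError("no onset month given")
    months = treated.months
    if onset <= months[0] or onset > months[-1]:
        raise ValueError("onset must lie strictly inside the month grid")

    n = len(months)
    T = np.arange(1, n + 1, dtype=float)
    X = (months >= onset).astype(float)
    onset_index = int(np.argmax(np.asarray(months >= onset)))
    Tpost = (T - T[onset_index]) if centering else T
    XT = X * Tpost

    def block(z: float, y: np.ndarray) -> np.ndarray:
        return np.column_stack([
            np.ones(n), T, X, XT,
            np.full(n, z), z * T, z * X, z * XT,
        ])

    design = np.vstack([block(1.0, treated.values), block(0.0, control.values)])
    y = np.concatenate([treated.values, control.values])
    return ItsaDesign(X=design, y=y, blocks=(slice(0, n), slice(n, 2 * n)),
                      months=months, onset=onset, onset_index=onset_index,
                      centering=centering)


def fit_ols(design: ItsaDesign) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients and residuals; errors on rank deficiency."""
    X, y = design.X, design.y
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the culprits via pivoted QR: pivoted-out columns have tiny R diagonal
        from scipy.linalg import qr
        _, R, piv = qr(X, mode="economic", pivoting=True)
        d = np.abs(np.diag(R))
        bad = [COEF_NAMES[piv[i]] if piv[i] < len(COEF_NAMES) else str(piv[i])
               for i in range(rank, X.shape[1])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, resid


def newey_west_cov(design: ItsaDesign, residuals: np.ndarray, lag: int) -> np.ndarray:
    """Bartlett-kernel HAC sandwich covariance of the OLS coefficients.

    meat = G0 + sum_{l=1..L} (1 - l/(L+1)) (G_l + G_l'), with G_l the lag-l
    cross-product of scores computed WITHIN each stacked series block (no
    lag term ever spans the treated/control boundary); bread is the inverse
    Gram matrix. lag=0 reduces to the heteroskedasticity-only sandwich.
    """
    X = design.X
    n = design.n_obs
    if lag < 0 or lag >= n:
        raise ValueError("lag must satisfy 0 <= lag < n_obs")
    gram = X.T @ X
    try:
        bread = np.linalg.inv(gram)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Gram matrix") from exc

    scores = X * residuals[:, None]
    k = X.shape[1]
    meat = np.zeros((k, k))
    for blk in design.blocks:
        g = scores[blk]
        m = g.shape[0]
        if m == 0:
            continue
        meat += g.T @ g
        for l in range(1, min(lag, m - 1) + 1):
            w = 1.0 - l / (lag + 1.0)
            gl = g[l:].T @ g[:-l]
            meat += w * (gl + gl.T)
    cov = bread @ meat @ bread
    return (cov + cov.T) / 2


def infer(t_stats: "np.ndarray | ItsaFit", df: int | None = None,
          alternative: str = "less") -> np.ndarray:
    """p-values for t-statistics against Student-t with the given df.

    Accepts either an array of t statistics plus ``df``, or a fitted
    :class:`ItsaFit` (its residual df is used). ``alternative``: 'less'
    (one-tailed, hypothesized decline), 'greater', or 'two-sided'.
    """
    if isinstance(t_stats, ItsaFit):
        df = t_stats.df_resid
        t_stats = t_stats.t
    if df is None:
        raise ValueError("df is required when passing raw t statistics")
    t_stats = np.asarray(t_stats, dtype=float)
    if alternative == "less":
        return stats.t.cdf(t_stats, df)
    if alternative == "greater":
        return stats.t.sf(t_stats, df)
    if alternative == "two-sided":
        return 2 * stats.t.sf(np.abs(t_stats), df)
    raise ValueError(f"unknown alternative {alternative!r}")


def fit_itsa(design: ItsaDesign, lag: int = 12,
             alternative: str = "less") -> ItsaFit:
    """OLS + Newey-West inference for the stacked design.

    The HAC lag defaults to 12 (one seasonal cycle of monthly data).
    One-tailed p-values use ``alternative`` for every coefficient; the
    default 'less' encodes the hypothesis that rates declined with the
    intervention. Two-tailed p-values are always reported alongside.
    """
    beta, resid = fit_ols(design)
    cov = newey_west_cov(design, resid, lag)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    df = design.n_obs - _DF_ADJUST
    if df <= 0:
        raise ValueError("not enough observations for inference")
    names = COEF_NAMES if design.X.shape[1] == 8 else COEF_NAMES[:design.X.shape[1]]
    return ItsaFit(beta=beta, hac_cov=cov, se=se, t=t,
                   p_one_tail=infer(t, df, alternative),
                   p_two_tail=infer(t, df, "two-sided"),
                   lag=lag, residuals=resid, n_obs=design.n_obs, names=names)


def balance(fit: ItsaFit, alpha: float = 0.05) -> BalanceReport:
    """Pre-period balance: are b4 (level gap) and b5 (trend gap) null?

    Balanced iff both two-tailed p-values exceed alpha; feeds the
    synthetic-control adequacy gate.
    """
    i4 = fit.names.index("b4_group")
    i5 = fit.names.index("b5_group_trend")
    p4 = float(fit.p_two_tail[i4])
    p5 = float(fit.p_two_tail[i5])
    return BalanceReport(beta4=float(fit.beta[i4]), beta5=float(fit.beta[i5]),
                         p4=p4, p5=p5, alpha=alpha,
                         balanced=bool(p4 > alpha and p5 > alpha))
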