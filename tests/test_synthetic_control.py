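import numpy as np
import pandas as pd
import pytest

from synthits._lasso import lasso_cd
from synthits.rates import RateSeries
from synthits.simulate import SimulationSpec, simulate_series
from synthits.synthetic_control import (
    CVSpec,
    PlaceboResult,
    assess_adequacy,
    build_donor_pool,
    fit_scul,
    placebo_test,
)


def make_series(values, cause="x", onset_index=60, start="2007-01", **kw):
    months = pd.period_range(start, periods=len(values), freq="M")
    return RateSeries(months=months, values=np.asarray(values, float),
                      cause=cause, onset=months[onset_index], **kw)


@pytest.fixture
def noiseless_world():
    spec = SimulationSpec(seed=7, sigma=0.0, n_donors=10)
    return simulate_series(spec)


class TestLassoSolver:
    def test_two_donor_solution_matches_dense_grid_search(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        X -= X.mean(axis=0)
        y = X @ np.array([0.8, -0.3]) + rng.normal(0, 0.2, 30)
        y -= y.mean()
        lam = 0.05
        beta = lasso_cd(X, y, lam)

        def objective(b):
            r = y - X @ b
            return 0.5 * r @ r / len(y) + lam * np.abs(b).sum()

        # coarse-to-fine dense grid search over the weight pair
        center, width = np.zeros(2), 2.0
        for _ in range(8):
            g1 = np.linspace(center[0] - width, center[0] + width, 41)
            g2 = np.linspace(center[1] - width, center[1] + width, 41)
            vals = np.array([[objective(np.array([a, b])) for b in g2] for a in g1])
            i, j = np.unravel_index(vals.argmin(), vals.shape)
            center, width = np.array([g1[i], g2[j]]), width / 10
        assert np.abs(beta - center).max() < 1e-6

    def test_matches_reference_lasso_implementation(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 8)); X -= X.mean(axis=0)
        y = X @ rng.normal(size=8) + rng.normal(0, 0.5, 60); y -= y.mean()
        for lam in (0.01, 0.1, 0.5):
            ours = lasso_cd(X, y, lam)
            ref = sklearn.Lasso(alpha=lam, fit_intercept=False, tol=1e-12,
                                max_iter=200_000).fit(X, y).coef_
            assert np.abs(ours - ref).max() < 1e-6

    def test_objective_is_nonincreasing_along_coordinate_updates(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6)); X -= X.mean(axis=0)
        y = rng.normal(size=40); y -= y.mean()
        trace = []
        lasso_cd(X, y, 0.05, objective_trace=trace)
        diffs = np.diff(trace)
        assert (diffs <= 1e-12).all()


class TestFitScul:
    def test_perfect_donor_is_reproduced(self, noiseless_world):
        _, pool, _ = noiseless_world
        treated = make_series(pool.series[3].values.copy(), cause="treated",
                              onset_index=84)
        fit = fit_scul(treated, pool.drop(3), onset=treated.onset, lam=0.0)
        assert fit.pre_rmspe < 1e-8
        # post prediction reproduces the copied donor as well
        post = ~treated.pre_mask()
        assert np.abs(fit.fitted.values[post] - treated.values[post]).max() < 1e-6

    def test_full_shrinkage_limit_fits_the_pre_period_mean(self, noiseless_world):
        treated, pool, _ = noiseless_world
        fit = fit_scul(treated, pool, lam=1e6)
        assert np.abs(fit.weights).max() == 0.0
        pre = treated.pre_mask()
        assert np.allclose(fit.fitted.values, treated.values[pre].mean())

    def test_deterministic_given_inputs(self):
        spec = SimulationSpec(seed=11, n_donors=12)
        treated, pool, _ = simulate_series(spec)
        f1 = fit_scul(treated, pool)
        f2 = fit_scul(treated, pool)
        assert np.array_equal(f1.weights, f2.weights)
        assert f1.lam == f2.lam

    def test_invariant_to_donor_ordering(self):
        spec = SimulationSpec(seed=11, n_donors=12)
        treated, pool, _ = simulate_series(spec)
        f1 = fit_scul(treated, pool)
        perm = np.arange(len(pool))[::-1]
        from synthits.synthetic_control import DonorPool
        pool2 = DonorPool([pool.series[i] for i in perm],
                          [pool.ids[i] for i in perm])
        f2 = fit_scul(treated, pool2)
        assert f1.lam == f2.lam
        # agreement up to the coordinate-descent stopping tolerance
        assert np.abs(f1.weights[perm] - f2.weights).max() < 1e-4
        assert np.abs(f1.fitted.values - f2.fitted.values).max() < 1e-4

    def test_nonzero_weights_bounded_by_pre_period_months(self):
        spec = SimulationSpec(seed=13)
        treated, pool, _ = simulate_series(spec)
        fit = fit_scul(treated, pool)
        assert fit.n_nonzero <= int(treated.pre_mask().sum())

    def test_too_short_pre_period_is_rejected(self):
        spec = SimulationSpec(seed=3, n_donors=5)
        treated, pool, _ = simulate_series(spec)
        with pytest.raises(ValueError, match="pre-onset months"):
            fit_scul(treated, pool, onset=treated.months[10])

    def test_degenerate_treated_variance_is_rejected(self, noiseless_world):
        _, pool, _ = noiseless_world
        flat = make_series(np.ones(132), onset_index=84)
        with pytest.raises(ValueError, match="zero pre-period variance"):
            fit_scul(flat, pool, onset=flat.onset)

    def test_fewer_than_two_donors_is_rejected(self, noiseless_world):
        treated, pool, _ = noiseless_world
        solo = pool.drop(0)
        while len(solo) > 1:
            solo = solo.drop(0)
        with pytest.raises(ValueError, match="2 donors"):
            fit_scul(treated, solo)


class TestDonorPool:
    def test_all_unrelated_candidates_are_kept(self):
        spec = SimulationSpec(seed=1, n_donors=33)
        treated, pool, _ = simulate_series(spec)
        rebuilt = build_donor_pool(pool.series, treated)
        assert len(rebuilt) == 33

    def test_treated_cause_is_self_excluded(self):
        spec = SimulationSpec(seed=1, n_donors=5)
        treated, pool, _ = simulate_series(spec)
        rebuilt = build_donor_pool(list(pool.series) + [treated], treated)
        assert len(rebuilt) == 5
        assert "treated series itself" in rebuilt.rejected.values()

    def test_exclusion_list_removes_named_causes(self):
        spec = SimulationSpec(seed=1, n_donors=5)
        treated, pool, _ = simulate_series(spec)
        rebuilt = build_donor_pool(pool.series, treated,
                                   exclusions=["donor_00", "donor_01"])
        assert len(rebuilt) == 3

    def test_composite_containing_treated_is_excluded(self, causes):
        spec = SimulationSpec(seed=1, n_donors=5)
        treated, pool, _ = simulate_series(spec)
        treated.cause = "ihd"
        composite_like = pool.series[0]
        composite_like.cause = "ihd_stroke"
        rebuilt = build_donor_pool(pool.series, treated, causes=causes)
        assert len(rebuilt) == 4
        assert any("composite" in why for why in rebuilt.rejected.values())

    def test_misaligned_donor_rejected_with_reason(self):
        spec = SimulationSpec(seed=1, n_donors=4)
        treated, pool, _ = simulate_series(spec)
        shifted = make_series(np.random.default_rng(0).normal(size=132),
                              cause="late", start="2007-02", onset_index=84)
        rebuilt = build_donor_pool(list(pool.series) + [shifted], treated)
        assert len(rebuilt) == 4
        assert "aligned" in rebuilt.rejected[shifted.label]

    def test_ineligible_series_rejected(self):
        spec = SimulationSpec(seed=1, n_donors=4)
        treated, pool, _ = simulate_series(spec)
        vals = pool.series[0].values.copy()
        vals[5] = np.nan
        broken = make_series(vals, cause="broken", onset_index=84)
        rebuilt = build_donor_pool(list(pool.series) + [broken], treated)
        assert len(rebuilt) == 4
        assert "ineligible" in rebuilt.rejected[broken.label]

    def test_empty_pool_is_an_error(self):
        spec = SimulationSpec(seed=1, n_donors=3)
        treated, pool, _ = simulate_series(spec)
        with pytest.raises(ValueError, match="empty donor pool"):
            build_donor_pool(pool.series, treated,
                             exclusions=["donor_00", "donor_01", "donor_02"])


class TestAdequacy:
    def test_perfect_fit_is_adequate_at_any_positive_threshold(self, noiseless_world):
        _, pool, _ = noiseless_world
        treated = make_series(pool.series[2].values.copy(), cause="treated",
                              onset_index=84)
        fit = fit_scul(treated, pool.drop(2), onset=treated.onset, lam=0.0)
        assert assess_adequacy(fit, threshold=1e-6)

    def test_white_noise_treated_is_inadequate(self):
        spec = SimulationSpec(seed=21, n_donors=10)
        _, pool, _ = simulate_series(spec)
        rng = np.random.default_rng(21)
        noise = make_series(rng.normal(0, 1, 132), cause="noise", onset_index=84)
        fit = fit_scul(noise, pool, onset=noise.onset)
        assert not assess_adequacy(fit, threshold=0.25)

    def test_zero_threshold_requires_exact_fit(self):
        spec = SimulationSpec(seed=22, n_donors=10)
        treated, pool, _ = simulate_series(spec)
        fit = fit_scul(treated, pool)
        assert not assess_adequacy(fit, threshold=0.0)

    def test_unbalanced_pre_period_fails_the_gate(self, noiseless_world):
        from synthits.itsa import BalanceReport
        _, pool, _ = noiseless_world
        treated = make_series(pool.series[2].values.copy(), cause="treated",
                              onset_index=84)
        fit = fit_scul(treated, pool.drop(2), onset=treated.onset, lam=0.0)
        bad_balance = BalanceReport(beta4=0.5, beta5=0.01, p4=0.001, p5=0.2,
                                    alpha=0.05, balanced=False)
        assert not assess_adequacy(fit, threshold=0.25, balance=bad_balance)


class TestPlacebo:
    @pytest.mark.parametrize("treated_ratio,placebos,expected", [
        (5.0, np.linspace(0.5, 2.0, 19), 1 / 20),   # treated largest of 19
        (0.1, np.linspace(0.5, 2.0, 19), 1.0),      # treated smallest
        (1.0, np.array([0.5, 1.0, 2.0]), 3 / 4),    # ties count as extreme
    ])
    def test_rank_p_arithmetic(self, treated_ratio, placebos, expected):
        res = PlaceboResult(treated_ratio=treated_ratio,
                            placebo_ratios=pd.Series(placebos),
                            n_filtered=0)
        assert res.rank_p == pytest.approx(expected)

    def test_large_injected_effect_yields_small_rank_p(self):
        spec = SimulationSpec(seed=30, n_donors=12, effect_level=-0.5,
                              treated_sigma=0.0)
        treated, pool, _ = simulate_series(spec)
        res = placebo_test(pool, treated)
        assert res.rank_p <= 0.25
        assert res.treated_ratio > res.placebo_ratios.median()
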