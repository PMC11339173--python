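"""Two-group interrupted time series with HAC inference and effect tables.

Runs the full estimation chain on simulated data with a known level effect
(-0.1 log points) and trend effect (-0.002/month): synthetic control, the
stacked segmented regression with Newey-West standard errors, pre-period
balance, and the effect conversions onto percent and absolute scales.
"""

from synthits import (
    SimulationSpec, balance, build_design, fit_itsa, fit_scul, report,
    simulate_series,
)

spec = SimulationSpec(seed=8, n_donors=30, effect_level=-0.1,
                      effect_trend=-0.002, treated_sigma=0.0)
treated, pool, _ = simulate_series(spec)

control = fit_scul(treated, pool).fitted
design = build_design(treated, control, treated.onset)
fit = fit_itsa(design, lag=12)

for name, b, se, p1 in zip(fit.names, fit.beta, fit.se, fit.p_one_tail):
    print(f"{name:<16} {b:+.4f}  (HAC se {se:.4f}, one-tail p {p1:.3f})")

bal = balance(fit)
print(f"pre-period balance: beta4 p={bal.p4:.2f}, beta5 p={bal.p5:.2f} "
      f"-> balanced={bal.balanced}")

table = report([{"cause": "simulated", "band": "20+", "fit": fit,
                 "reference_rate": 9.0, "reference_kind": "post_mean"}])
print(table[["effect", "coefficient", "percent", "absolute_per_100k",
             "stars"]].to_string(index=False))
# b6 ~ -0.1 is read as a ~10% immediate drop (absolute: 9.0 x -0.1 ~ -0.9
# events per 100 000); b7 ~ -0.002 is a 0.2%/month steepening decline.
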