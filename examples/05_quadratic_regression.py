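"""Quadratic fixed-effects logistic regression of statin initiation.

Fits the initiation model on simulated provider-encounter rows, compares
linear vs quadratic specifications with a clustered Wald test, reports
the curvature vertices (inflection points), average marginal effects,
and the 1% trimming sensitivity.
"""

import cogload as cl

cfg = cl.SimulationConfig(n_patients=4000, n_providers=40, seed=31)
data = cl.simulate_outcomes(cl.simulate_metrics(cfg, n_encounters=4000), seed=32)

fit = cl.fit_model(data)  # quadratic in loops and distinct events
linear = cl.fit_model(
    data, cl.ModelSpec(metric_quadratic={m: False for m in cl.ModelSpec().metrics})
)

print(f"n observations: {fit.n_obs}; in-sample AUROC: {fit.auroc:.3f}")
print("\nmetric coefficients (clustered SEs):")
print(fit.summary_frame().loc[
    ["loops", "loops_sq", "distinct_events", "distinct_events_sq",
     "duration_minutes", "avg_event_seconds"]
].round(5).to_string())

wald = cl.wald_compare(linear, fit)
print(f"\nWald test of the quadratic terms: stat={wald.statistic:.1f}, "
      f"df={wald.df}, p={wald.p_value:.2e} -> {wald.recommendation}")

for metric, vertex in fit.inflection_points().items():
    print(f"inflection point for {metric}: {vertex:.1f}")

ame = cl.average_marginal_effects(fit, "loops", n_grid=9)
print("\naverage marginal effect of loop count:")
print(ame.round(4).to_string(index=False))

trim = cl.trim_sensitivity(data, full_fit=fit)
print(f"\n1% trim sensitivity: {trim.stability['stable'].mean() * 100:.0f}% of "
      "metric terms stable in sign and significance across the four trims")
print()
print("The AME changes sign where the quadratic contribution has its vertex:")
print("initiation probability falls with each extra loop below the vertex")
print("and rises above it (a U shape), while distinct events show the")
print("opposite, inverse-U pattern.")
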