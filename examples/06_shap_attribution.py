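"""Event-level SHAP attribution of a boosted statin-initiation model.

Builds the encounter-level event-by-metric feature matrix from a
simulated audit log, trains repeated early-stopped gradient-boosted
models on the simulated outcomes, and ranks features by global mean
|SHAP| with across-run significance filtering.  Also demonstrates the
pre-decision truncation sensitivity.
"""

import cogload as cl

cfg = cl.SimulationConfig(
    n_patients=600, n_providers=25, event_vocabulary_size=40, seed=55
)
study = cl.simulate_study(cfg)
vocab = [f"EV{i:03d}" for i in range(40)]
cov = (
    study.ground_truth.groupby("csn")
    .first()
    .reset_index()[
        ["csn", "age", "sex", "race_ethnicity", "insurance_class",
         "n_active_diagnoses", "elixhauser"]
    ]
)
fm = cl.build_features(
    study.audit_log, cov, vocab,
    provider_types=study.providers.set_index("provider_id")["provider_type"],
)
y = study.encounters.set_index("csn").loc[fm.data.index, "initiated"].to_numpy()

trained = cl.train_repeated(fm.X, y, n_repeats=10, seed=56)
print(f"test AUROC over {len(trained.runs)} repeats: "
      f"{trained.test_aurocs.mean():.3f} +/- {trained.test_aurocs.std():.3f}")

summary = cl.summarize_shap(trained, fm.X)
cols = ["rank", "event", "metric_kind", "mean_shap", "global_mean_shap",
        "direction", "relative_contribution_pct", "cumulative_contribution_pct"]
print("\ntop significant features (ranked by global mean |SHAP|):")
print(summary.table[cols].head(10).round(4).to_string(index=False))

rule = cl.TruncationRule(mode="pre_decision", order_screen_event="EV005")
res = cl.apply_truncation(study.audit_log, study.encounters, rule)
print(f"\npre-decision truncation removed {res.n_removed} of "
      f"{len(study.audit_log)} events "
      f"(fallback median time-to-order {res.fallback_median_seconds / 60:.1f} min)")
print()
print("Each event type contributes three features (average dwell, loops,")
print("shown); the significance filter keeps features whose mean SHAP CI")
print("excludes zero, and relative contributions normalise global mean")
print("|SHAP| over that significant set. With outcomes generated from the")
print("encounter-level metrics, attribution spreads across many correlated")
print("event columns rather than concentrating on one.")
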