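"""Event-level feature construction, truncation, boosted training, SHAP ranking."""

import numpy as np
import pandas as pd
import pytest

import cogload as cl
from cogload._treeshap import shap_values
from cogload.attribution import BoostedRun, RepeatedTrainResult, _staged_margin
from cogload.errors import SpecificationError

from conftest import make_audit_log


@pytest.fixture(scope="module")
def tiny_log():
    # one provider, one encounter: A(2s) B(4s) A(6s); a second CSN event
    # caps the final dwell at 6s instead of the timeout
    rows = [
        ("p1", "c1", "A", "2024-03-01 09:00:00"),
        ("p1", "c1", "B", "2024-03-01 09:00:02"),
        ("p1", "c1", "A", "2024-03-01 09:00:06"),
        ("p1", "c2", "X", "2024-03-01 09:00:12"),
    ]
    return make_audit_log(rows)


@pytest.fixture(scope="module")
def tiny_cov():
    return pd.DataFrame(
        {
            "csn": ["c1", "c2"],
            "age": [60.0, 50.0],
            "sex": ["male", "female"],
            "race_ethnicity": ["White", "Asian"],
            "insurance_class": ["commercial", "non-commercial"],
            "n_active_diagnoses": [5, 7],
            "elixhauser": [1, 0],
        }
    )


class TestBuildFeatures:
    def test_hand_computed_event_features(self, tiny_log, tiny_cov):
        fm = cl.build_features(tiny_log, tiny_cov, ["A", "B", "X"])
        row = fm.data.loc["c1"]
        assert row["A::avg_seconds"] == pytest.approx(4.0)  # (2 + 6) / 2
        assert row["A::loops"] == 1.0
        assert row["A::shown"] == 1.0
        assert row["B::avg_seconds"] == pytest.approx(4.0)
        assert row["B::loops"] == 0.0
        assert row["B::shown"] == 1.0

    def test_absent_events_are_all_zero(self, tiny_log, tiny_cov):
        fm = cl.build_features(tiny_log, tiny_cov, ["A", "B", "X", "Z"])
        assert (fm.data.loc["c1", ["Z::avg_seconds", "Z::loops", "Z::shown"]] == 0).all()
        # shown = 0 implies time and loop columns are 0, matrix-wide
        for ev in ["A", "B", "X", "Z"]:
            hidden = fm.data[f"{ev}::shown"] == 0
            assert (fm.data.loc[hidden, f"{ev}::avg_seconds"] == 0).all()
            assert (fm.data.loc[hidden, f"{ev}::loops"] == 0).all()

    def test_vocabulary_of_215_types_yields_645_columns(self, tiny_log, tiny_cov):
        vocab = [f"EV{i:03d}" for i in range(215)]
        fm = cl.build_features(tiny_log, tiny_cov, vocab)
        assert len(fm.event_columns) == 645
        assert fm.overflow_events == ["A", "B", "X"]

    def test_provider_type_indicators(self, small_study):
        cov = (
            small_study.ground_truth.groupby("csn")
            .first()
            .reset_index()[
                ["csn", "age", "sex", "race_ethnicity", "insurance_class",
                 "n_active_diagnoses", "elixhauser"]
            ]
        )
        vocab = [f"EV{i:03d}" for i in range(40)]
        fm = cl.build_features(
            small_study.audit_log,
            cov,
            vocab,
            provider_types=small_study.providers.set_index("provider_id")["provider_type"],
        )
        assert {"has_physician", "has_np", "has_pa"} <= set(fm.covariate_columns)
        assert fm.data[["has_physician", "has_np", "has_pa"]].to_numpy().max() == 1.0


class TestTruncation:
    def _outcomes(self, rows):
        return pd.DataFrame(
            {
                "csn": [r[0] for r in rows],
                "initiated": [r[1] for r in rows],
                "order_time": pd.to_datetime([r[2] for r in rows]),
            }
        )

    def test_full_mode_is_identity(self, small_study):
        rule = cl.TruncationRule(mode="full")
        res = cl.apply_truncation(small_study.audit_log, small_study.encounters, rule)
        assert res.n_removed == 0
        pd.testing.assert_frame_equal(res.events, small_study.audit_log)

    def test_initiated_cut_at_order_time(self):
        rows = [("p1", "c1", "A", f"2024-03-01 09:{m:02d}:00") for m in range(0, 30, 2)]
        log = make_audit_log(rows)
        out = self._outcomes([("c1", True, "2024-03-01 09:12:00")])
        res = cl.apply_truncation(log, out, cl.TruncationRule(mode="pre_decision"))
        assert (res.events["timestamp"] <= pd.Timestamp("2024-03-01 09:12:00")).all()
        assert res.n_removed == len(log) - len(res.events) > 0

    def test_fallback_median_time_to_order(self):
        rows = (
            [("p1", "c1", "A", "2024-03-01 09:00:00"), ("p1", "c1", "B", "2024-03-01 09:15:00")]
            + [("p2", "c2", "A", "2024-03-01 10:00:00"), ("p2", "c2", "B", "2024-03-01 10:25:00")]
            + [("p3", "c3", "A", "2024-03-01 11:00:00"), ("p3", "c3", "B", "2024-03-01 11:20:00")]
        )
        log = make_audit_log(rows)
        out = self._outcomes(
            [
                ("c1", True, "2024-03-01 09:10:00"),   # 10 min to order
                ("c2", True, "2024-03-01 10:20:00"),   # 20 min to order
                ("c3", False, None),
            ]
        )
        res = cl.apply_truncation(log, out, cl.TruncationRule(mode="pre_decision"))
        assert res.fallback_median_seconds == pytest.approx(15 * 60.0)
        # c3 cut at start + 15 min => the 11:20 event is dropped
        assert res.cut_times["c3"] == pd.Timestamp("2024-03-01 11:15:00")
        kept_c3 = res.events[res.events.csn == "c3"]
        assert list(kept_c3["event_type"]) == ["A"]

    def test_order_screen_event_takes_precedence(self):
        rows = [
            ("p1", "c1", "A", "2024-03-01 09:00:00"),
            ("p1", "c1", "ORDER_SCREEN", "2024-03-01 09:05:00"),
            ("p1", "c1", "B", "2024-03-01 09:09:00"),
            ("p2", "c2", "A", "2024-03-01 10:00:00"),
        ]
        log = make_audit_log(rows)
        out = self._outcomes([("c1", False, None), ("c2", True, "2024-03-01 10:01:00")])
        rule = cl.TruncationRule(mode="pre_decision", order_screen_event="ORDER_SCREEN")
        res = cl.apply_truncation(log, out, rule)
        assert res.cut_times["c1"] == pd.Timestamp("2024-03-01 09:05:00")
        assert "B" not in set(res.events.query("csn == 'c1'")["event_type"])

    def test_initiated_without_order_time_is_an_error(self):
        log = make_audit_log([("p1", "c1", "A", "2024-03-01 09:00:00")])
        out = self._outcomes([("c1", True, None)])
        with pytest.raises(SpecificationError, match="order timestamp"):
            cl.apply_truncation(log, out, cl.TruncationRule(mode="pre_decision"))

    def test_pre_decision_features_are_censored_monotonically(self, small_study):
        """Loop counts, shown flags, and per-type total active time never
        exceed their full-encounter values after pre-decision truncation."""
        vocab = [f"EV{i:03d}" for i in range(40)]
        cov = (
            small_study.ground_truth.groupby("csn")
            .first()
            .reset_index()[
                ["csn", "age", "sex", "race_ethnicity", "insurance_class",
                 "n_active_diagnoses", "elixhauser"]
            ]
        )
        full = cl.build_features(small_study.audit_log, cov, vocab)
        rule = cl.TruncationRule(mode="pre_decision", order_screen_event="EV001")
        res = cl.apply_truncation(small_study.audit_log, small_study.encounters, rule)
        pre = cl.build_features(res.events, cov, vocab, cut_times=res.cut_times)
        loops = [c for c in full.event_columns if c.endswith("::loops")]
        shown = [c for c in full.event_columns if c.endswith("::shown")]
        avg = [c for c in full.event_columns if c.endswith("::avg_seconds")]
        assert (pre.data[loops].to_numpy() <= full.data[loops].to_numpy() + 1e-9).all()
        assert (pre.data[shown].to_numpy() <= full.data[shown].to_numpy() + 1e-9).all()
        count_full = full.data[loops].to_numpy() + full.data[shown].to_numpy()
        count_pre = pre.data[loops].to_numpy() + pre.data[shown].to_numpy()
        total_full = full.data[avg].to_numpy() * count_full
        total_pre = pre.data[avg].to_numpy() * count_pre
        assert (total_pre <= total_full + 1e-6).all()


@pytest.fixture(scope="module")
def noise_matrix():
    rng = np.random.default_rng(5)
    return pd.DataFrame(rng.normal(size=(300, 12)), columns=[f"f{j}" for j in range(12)])


class TestTrainRepeated:
    def test_deterministic_under_seed(self, noise_matrix):
        y = (noise_matrix["f0"] > 0).astype(int).to_numpy()
        a = cl.train_repeated(noise_matrix, y, n_repeats=3, seed=4, max_rounds=40)
        b = cl.train_repeated(noise_matrix, y, n_repeats=3, seed=4, max_rounds=40)
        assert np.array_equal(a.test_aurocs, b.test_aurocs)
        assert [r.n_trees for r in a.runs] == [r.n_trees for r in b.runs]

    def test_learnable_outcome_reaches_high_auroc(self, noise_matrix):
        y = (noise_matrix["f3"] > noise_matrix["f3"].median()).astype(int).to_numpy()
        res = cl.train_repeated(noise_matrix, y, n_repeats=5, seed=1, max_rounds=80)
        assert res.test_aurocs.mean() >= 0.99

    def test_pure_noise_outcome_hovers_at_chance(self, noise_matrix):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, len(noise_matrix))
        res = cl.train_repeated(noise_matrix, y, n_repeats=20, seed=2, max_rounds=40)
        assert 0.45 <= res.test_aurocs.mean() <= 0.55

    def test_early_stopping_respects_budget(self, noise_matrix):
        y = (noise_matrix["f0"] > 0).astype(int).to_numpy()
        res = cl.train_repeated(noise_matrix, y, n_repeats=2, seed=3, max_rounds=25)
        assert all(1 <= r.n_trees <= 25 for r in res.runs)

    def test_staged_margin_matches_decision_function_at_full_depth(self, noise_matrix):
        y = (noise_matrix["f0"] > 0).astype(int).to_numpy()
        res = cl.train_repeated(noise_matrix, y, n_repeats=1, seed=6, max_rounds=15)
        run = res.runs[0]
        X = noise_matrix.to_numpy()
        full = run.model.decision_function(X[:20])
        staged = _staged_margin(run.model, X[:20], len(run.model.estimators_))
        assert np.allclose(full, staged, atol=1e-10)


class TestSummarizeShap:
    def _biased_runs(self):
        """Runs whose test rows are deliberately shifted so the causal
        feature has a stable nonzero mean SHAP — exercises aggregation,
        significance, normalisation and ranking logic."""
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(400, 6)), columns=[f"f{j}" for j in range(6)])
        y = (X["f1"] + 0.6 * rng.normal(size=400) > 0).astype(int).to_numpy()
        trained = cl.train_repeated(X, y, n_repeats=8, seed=8, max_rounds=60)
        high = np.flatnonzero(X["f1"].to_numpy() > 0.5)
        runs = [
            BoostedRun(
                seed=r.seed,
                model=r.model,
                n_trees=r.n_trees,
                test_index=high[(i * 8): (i * 8 + 40)],
                test_auroc=r.test_auroc,
            )
            for i, r in enumerate(trained.runs)
        ]
        return RepeatedTrainResult(runs=runs, feature_names=trained.feature_names), X

    def test_significant_table_normalisation_and_ranking(self):
        trained, X = self._biased_runs()
        summary = cl.summarize_shap(trained, X)
        table = summary.table
        assert len(table) >= 1
        assert table["relative_contribution_pct"].sum() == pytest.approx(100.0, abs=0.01)
        assert (table["global_mean_shap"].diff().dropna() <= 1e-12).all()
        assert np.allclose(
            table["cumulative_contribution_pct"],
            table["relative_contribution_pct"].cumsum(),
            atol=0.01,
        )
        # significance definition: CI excludes zero
        assert ((table["ci_lower"] > 0) | (table["ci_upper"] < 0)).all()

    def test_single_significant_feature_gets_full_contribution(self):
        trained, X = self._biased_runs()
        summary = cl.summarize_shap(trained, X)
        if len(summary.table) == 1:
            assert summary.table["relative_contribution_pct"].iloc[0] == pytest.approx(100.0)
        else:  # keep only the top significant feature and re-normalise
            top = summary.table.iloc[0]
            assert top["relative_contribution_pct"] <= 100.0
            assert top["feature"] == "f1"

    def test_additivity_within_pipeline(self):
        trained, X = self._biased_runs()
        run = trained.runs[0]
        Xa = np.asarray(X, dtype=np.float64)
        phi, base = shap_values(run.model, Xa[run.test_index], n_trees=run.n_trees)
        margin = _staged_margin(run.model, Xa[run.test_index], run.n_trees)
        assert np.abs(phi.sum(axis=1) + base - margin).max() < 1e-4

    def test_too_few_runs_rejected(self):
        trained, X = self._biased_runs()
        solo = RepeatedTrainResult(runs=trained.runs[:1], feature_names=trained.feature_names)
        with pytest.raises(SpecificationError):
            cl.summarize_shap(solo, X)

    def test_relative_contributions_are_scale_free(self):
        # multiplying all global means by a constant leaves contributions fixed
        trained, X = self._biased_runs()
        a = cl.summarize_shap(trained, X).table
        g = a["global_mean_shap"].to_numpy()
        rel_scaled = 100.0 * (3.7 * g) / (3.7 * g).sum()
        assert np.allclose(rel_scaled, a["relative_contribution_pct"], atol=1e-9)
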