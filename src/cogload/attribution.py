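"""Event-level feature construction, repeated boosted training, and SHAP
attribution of statin initiation.

Each analytic row is a single encounter.  For every event type in the
vocabulary three features are built from the encounter's pooled merged
event stream: the average active time per occurrence (seconds), the
number of loops back to that event type (revisit occurrences), and a
shown indicator.  Encounters that never touch an event type carry zeros
in all three columns.  Patient covariates and provider-type indicator
columns (physician / NP / PA participated) complete the matrix.

The model is a logistic-objective gradient-boosted tree ensemble
trained under a repeated 70/15/15 train/validation/test split: up to
300 boosting rounds with early stopping after 10 rounds without
validation-AUROC improvement, the best-validation model scored on the
held-out test set, the whole procedure repeated with fresh splits.
SHAP values are computed per repeat on that repeat's test rows; a
feature is significant when the 95% CI of its mean SHAP value (across
repeats by default) excludes zero, and significant features are ranked
by global mean |SHAP| with relative and cumulative contributions.

A pre-decision sensitivity truncates each encounter's event stream at
the statin order time (initiated) or at the first medication-order
screen, falling back to the initiated encounters' median time-to-order
(non-initiated), to remove post-decision artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score

from ._treeshap import shap_values
from .config import RACE_LEVELS
from .errors import ConfigurationError, SpecificationError
from .metrics import pooled_encounter_streams

METRIC_KIND_LABELS = {
    "avg_seconds": "Average Time Per Event (sec)",
    "loops": "Number of Loops",
    "shown": "Event Shown (1/0)",
}

DEFAULT_COVARIATES = ("age", "n_active_diagnoses", "elixhauser")
DEFAULT_CATEGORICAL = ("sex", "race_ethnicity", "insurance_class")


@dataclass
class FeatureMatrix:
    """One row per encounter: 3 columns per vocabulary event + covariates."""

    data: pd.DataFrame  # indexed by csn
    event_columns: list
    covariate_columns: list
    overflow_events: list = field(default_factory=list)

    @property
    def X(self) -> pd.DataFrame:
        return self.data[self.event_columns + self.covariate_columns]


def _encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=covariates.index)
    for col in DEFAULT_COVARIATES:
        if col in covariates.columns:
            out[col] = covariates[col].astype(float)
    if "sex" in covariates.columns:
        out["sex_female"] = (covariates["sex"] == "female").astype(float)
    if "race_ethnicity" in covariates.columns:
        for level in RACE_LEVELS[1:]:
            out[f"race_{level}"] = (covariates["race_ethnicity"] == level).astype(float)
    if "insurance_class" in covariates.columns:
        out["insurance_non_commercial"] = (
            covariates["insurance_class"] == "non-commercial"
        ).astype(float)
    return out


def build_features(
    audit_log: pd.DataFrame,
    covariates: pd.DataFrame,
    vocabulary,
    provider_types: pd.Series | None = None,
    timeout: float = 600.0,
    cut_times: pd.Series | None = None,
) -> FeatureMatrix:
    """Build the encounter-level event-by-metric feature matrix.

    Parameters
    ----------
    audit_log
        Raw audit-log rows (possibly already truncated).
    covariates
        One row per encounter, indexed by or containing ``csn``, with the
        patient covariate columns.
    vocabulary
        Event types to expand into columns (3 columns per type, in
        vocabulary order).  Event types found in the log but absent from
        the vocabulary go to ``overflow_events`` and get no columns.
    provider_types
        Mapping provider_id -> {"physician", "NP", "PA"}; adds the three
        participation indicator columns.
    cut_times
        Optional per-encounter censoring times: each pooled event's
        active seconds are capped at (cut - event time) so no active time
        beyond the cut is counted.
    """
    vocabulary = list(vocabulary)
    if len(vocabulary) == 0:
        raise ConfigurationError("event vocabulary must be non-empty")
    cov = covariates.set_index("csn") if "csn" in covariates.columns else covariates
    pooled = pooled_encounter_streams(audit_log, timeout=timeout)
    if cut_times is not None and not pooled.empty:
        cut = pooled["csn"].map(cut_times)
        remaining = (cut - pooled["timestamp"]).dt.total_seconds()
        cap = remaining.where(cut.notna(), np.inf).clip(lower=0.0)
        pooled["active_seconds"] = np.minimum(pooled["active_seconds"], cap)

    vocab_set = set(vocabulary)
    overflow = sorted(set(pooled["event_type"]) - vocab_set) if not pooled.empty else []
    if overflow:
        pooled = pooled[pooled["event_type"].isin(vocab_set)]

    index = cov.index
    frame = pd.DataFrame(index=index, dtype=float)
    if pooled.empty:
        agg = pd.DataFrame(columns=["csn", "event_type", "n", "avg"])
    else:
        agg = (
            pooled.groupby(["csn", "event_type"])["active_seconds"]
            .agg(n="count", avg="mean")
            .reset_index()
        )
    avg = agg.pivot(index="csn", columns="event_type", values="avg")
    cnt = agg.pivot(index="csn", columns="event_type", values="n")
    event_columns = []
    blocks = {}
    for ev in vocabulary:
        a = avg[ev].reindex(index).fillna(0.0) if ev in avg.columns else pd.Series(0.0, index=index)
        c = cnt[ev].reindex(index).fillna(0.0) if ev in cnt.columns else pd.Series(0.0, index=index)
        blocks[f"{ev}::avg_seconds"] = a.astype(float)
        blocks[f"{ev}::loops"] = np.maximum(c - 1.0, 0.0)
        blocks[f"{ev}::shown"] = (c > 0).astype(float)
        event_columns += [f"{ev}::avg_seconds", f"{ev}::loops", f"{ev}::shown"]
    frame = pd.concat([frame, pd.DataFrame(blocks, index=index)], axis=1)

    cov_enc = _encode_covariates(cov)
    covariate_columns = list(cov_enc.columns)
    frame = frame.join(cov_enc)
    if provider_types is not None and not pooled.empty:
        ptype = pooled.assign(ptype=pooled["provider_id"].map(provider_types))
        present = ptype.groupby("csn")["ptype"].agg(set)
        for label, col in (("physician", "has_physician"), ("NP", "has_np"), ("PA", "has_pa")):
            frame[col] = (
                present.reindex(index).map(lambda s, lb=label: float(lb in s) if isinstance(s, set) else 0.0)
            )
            covariate_columns.append(col)
    frame = frame.fillna(0.0)
    return FeatureMatrix(
        data=frame,
        event_columns=event_columns,
        covariate_columns=covariate_columns,
        overflow_events=overflow,
    )


@dataclass(frozen=True)
class TruncationRule:
    """How to censor encounter streams for the pre-decision sensitivity."""

    mode: str = "full"  # "full" | "pre_decision"
    order_screen_event: str | None = None

    def __post_init__(self):
        if self.mode not in ("full", "pre_decision"):
            raise ConfigurationError(f"truncation mode {self.mode!r} not recognised")


@dataclass
class TruncationResult:
    events: pd.DataFrame
    cut_times: pd.Series  # per csn; NaT where no cut applies
    fallback_median_seconds: float | None
    n_removed: int


def apply_truncation(
    audit_log: pd.DataFrame, outcomes: pd.DataFrame, rule: TruncationRule
) -> TruncationResult:
    """Censor event streams at the decision point.

    Initiated encounters are cut at the first statin order timestamp
    (missing timestamp is a data-integrity error).  Non-initiated
    encounters are cut at their first medication-order-screen event, or,
    when no such event occurs, at encounter start plus the median
    time-to-order observed among initiated encounters.  Events strictly
    after the cut are removed.
    """
    if rule.mode == "full":
        cuts = pd.Series(pd.NaT, index=pd.Index(outcomes["csn"], name="csn"))
        return TruncationResult(audit_log.copy(), cuts, None, 0)

    out = outcomes.set_index("csn")
    starts = audit_log.groupby("csn")["timestamp"].min()
    initiated = out[out["initiated"].astype(bool)]
    if initiated["order_time"].isna().any():
        bad = initiated.index[initiated["order_time"].isna()].tolist()
        raise SpecificationError(
            f"initiated encounters without an order timestamp: {bad[:5]}"
        )
    deltas = (
        pd.to_datetime(initiated["order_time"]) - starts.reindex(initiated.index)
    ).dt.total_seconds()
    median_delta = float(deltas.median()) if len(deltas) else None

    cuts = {}
    for csn, row in out.iterrows():
        if bool(row["initiated"]):
            cuts[csn] = pd.Timestamp(row["order_time"])
            continue
        cut = pd.NaT
        if rule.order_screen_event is not None:
            sub = audit_log[
                (audit_log["csn"] == csn)
                & (audit_log["event_type"] == rule.order_screen_event)
            ]
            if len(sub):
                cut = sub["timestamp"].min()
        if pd.isna(cut):
            if median_delta is None:
                raise SpecificationError(
                    "no initiated encounters to derive the median time-to-order from"
                )
            cut = starts.get(csn, pd.NaT)
            if not pd.isna(cut):
                cut = cut + pd.Timedelta(seconds=median_delta)
        cuts[csn] = cut
    cut_series = pd.Series(cuts, name="cut_time")
    cut_series.index.name = "csn"

    mapped = audit_log["csn"].map(cut_series)
    keep = mapped.isna() | (audit_log["timestamp"] <= mapped)
    events = audit_log[keep].reset_index(drop=True)
    return TruncationResult(
        events=events,
        cut_times=cut_series,
        fallback_median_seconds=median_delta,
        n_removed=int((~keep).sum()),
    )


@dataclass
class BoostedRun:
    seed: int
    model: GradientBoostingClassifier
    n_trees: int
    test_index: np.ndarray
    test_auroc: float
    n_retries: int = 0


@dataclass
class RepeatedTrainResult:
    runs: list
    feature_names: list

    @property
    def test_aurocs(self) -> np.ndarray:
        return np.array([r.test_auroc for r in self.runs])


def _split_indices(rng, n, val_frac, test_frac):
    perm = rng.permutation(n)
    n_test = int(round(test_frac * n))
    n_val = int(round(val_frac * n))
    return perm[n_test + n_val :], perm[n_test : n_test + n_val], perm[:n_test]


def train_repeated(
    X,
    y,
    n_repeats: int = 200,
    val_fraction: float = 0.15,
    test_fraction: float = 0.15,
    max_rounds: int = 300,
    patience: int = 10,
    seed: int = 0,
    learning_rate: float = 0.1,
    max_depth: int = 6,
    subsample: float = 1.0,
) -> RepeatedTrainResult:
    """Repeated 70/15/15 boosted training with validation-AUROC early stop.

    Each repeat draws a fresh random split at the encounter level, grows
    trees one at a time up to ``max_rounds``, stops once ``patience``
    successive rounds fail to improve the validation AUROC, and scores
    the best-validation model on the held-out test rows.  Splits lacking
    a class are redrawn (logged per run).  Fully deterministic under
    ``seed``.
    """
    feature_names = list(X.columns) if hasattr(X, "columns") else [
        f"x{j}" for j in range(np.asarray(X).shape[1])
    ]
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 20:
        raise SpecificationError("too few rows for a 70/15/15 split")
    master = np.random.default_rng(seed)
    run_seeds = master.integers(0, 2**31 - 1, size=n_repeats)
    runs = []
    for r in range(n_repeats):
        rng = np.random.default_rng(int(run_seeds[r]))
        retries = 0
        while True:
            tr, va, te = _split_indices(rng, n, val_fraction, test_fraction)
            ok = all(len(np.unique(y[idx])) == 2 for idx in (tr, va, te))
            if ok:
                break
            retries += 1
            if retries > 50:
                raise SpecificationError("could not draw a split containing both classes")
        model = GradientBoostingClassifier(
            learning_rate=learning_rate,
            max_depth=max_depth,
            subsample=subsample,
            n_estimators=1,
            warm_start=True,
            random_state=int(run_seeds[r]) % (2**31 - 1),
        )
        best_auc, best_iter, since_best = -np.inf, 0, 0
        for t in range(1, max_rounds + 1):
            model.n_estimators = t
            model.fit(X[tr], y[tr])
            val_margin = model.decision_function(X[va])
            auc = roc_auc_score(y[va], val_margin)
            if auc > best_auc:
                best_auc, best_iter, since_best = auc, t, 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        test_margin = _staged_margin(model, X[te], best_iter)
        runs.append(
            BoostedRun(
                seed=int(run_seeds[r]),
                model=model,
                n_trees=best_iter,
                test_index=te,
                test_auroc=float(roc_auc_score(y[te], test_margin)),
                n_retries=retries,
            )
        )
    return RepeatedTrainResult(runs=runs, feature_names=feature_names)


def _staged_margin(model, X, n_trees):
    """Margin using only the first ``n_trees`` boosting stages."""
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    full = np.asarray(model.decision_function(X[:1])).ravel()[0]
    all_part = sum(model.learning_rate * t.predict(X[:1]) for t in model.estimators_[:, 0])
    init = full - np.asarray(all_part).ravel()[0]
    margin = np.full(X.shape[0], init)
    for t in model.estimators_[:n_trees, 0]:
        margin += model.learning_rate * t.predict(X)
    return margin


@dataclass
class ShapSummary:
    """Across-run SHAP aggregation mirroring a ranked attribution table.

    ``table`` holds the significant features ranked by global mean
    |SHAP|, with 95% CI of the mean SHAP, direction, and relative /
    cumulative contribution percentages (summing to 100 over the
    significant set).  ``all_features`` keeps every feature's statistics
    before filtering.
    """

    table: pd.DataFrame
    all_features: pd.DataFrame
    test_aurocs: np.ndarray


def _feature_labels(name: str):
    if "::" in name:
        ev, kind = name.split("::", 1)
        return ev, METRIC_KIND_LABELS.get(kind, kind)
    return name, "Covariate"


def summarize_shap(
    trained: RepeatedTrainResult,
    X,
    ci_level: float = 0.95,
    ci_across: str = "runs",
) -> ShapSummary:
    """Aggregate per-run test-set SHAP values into a significance-ranked table.

    SHAP values are computed for each run's early-stopped model on that
    run's held-out test rows.  Per feature, the mean SHAP value carries
    direction and the global mean SHAP (mean |SHAP|) carries magnitude;
    the CI of the mean is a t-interval across run-level means (default)
    or across pooled test observations (``ci_across="observations"``).
    Features that are non-significant or identically zero are filtered;
    relative contributions normalise global means over the significant
    set.
    """
    if len(trained.runs) < 2:
        raise SpecificationError("need at least two runs to form a confidence interval")
    if ci_across not in ("runs", "observations"):
        raise ConfigurationError("ci_across must be 'runs' or 'observations'")
    Xa = np.asarray(X, dtype=np.float64)
    p = Xa.shape[1]
    run_means = np.zeros((len(trained.runs), p))
    run_gmeans = np.zeros((len(trained.runs), p))
    pooled_rows = []
    for i, run in enumerate(trained.runs):
        phi, _ = shap_values(run.model, Xa[run.test_index], n_trees=run.n_trees)
        run_means[i] = phi.mean(axis=0)
        run_gmeans[i] = np.abs(phi).mean(axis=0)
        if ci_across == "observations":
            pooled_rows.append(phi)

    mean_shap = run_means.mean(axis=0)
    global_mean = run_gmeans.mean(axis=0)
    alpha = 1.0 - ci_level
    if ci_across == "runs":
        sd = run_means.std(axis=0, ddof=1)
        n_runs = len(trained.runs)
        tcrit = stats.t.ppf(1 - alpha / 2, n_runs - 1)
        half = tcrit * sd / np.sqrt(n_runs)
    else:
        pooled = np.vstack(pooled_rows)
        sd = pooled.std(axis=0, ddof=1)
        tcrit = stats.t.ppf(1 - alpha / 2, pooled.shape[0] - 1)
        half = tcrit * sd / np.sqrt(pooled.shape[0])
        mean_shap = pooled.mean(axis=0)
    ci_lower = mean_shap - half
    ci_upper = mean_shap + half
    significant = ((ci_lower > 0) | (ci_upper < 0)) & (global_mean > 0)

    events, kinds = zip(*(_feature_labels(f) for f in trained.feature_names))
    allf = pd.DataFrame(
        {
            "feature": trained.feature_names,
            "event": events,
            "metric_kind": kinds,
            "mean_shap": mean_shap,
            "global_mean_shap": global_mean,
            "ci_lower": ci_lower,
            "ci_upper": ci_upper,
            "significant": significant,
            "direction": np.where(mean_shap > 0, "Positive", np.where(mean_shap < 0, "Negative", "Zero")),
        }
    )
    sig = allf[allf["significant"]].copy()
    if sig.empty:
        warnings.warn("no significant features; attribution table is empty")
        table = sig.assign(rank=[], relative_contribution_pct=[], cumulative_contribution_pct=[])
    else:
        sig = sig.sort_values("global_mean_shap", ascending=False).reset_index(drop=True)
        total = sig["global_mean_shap"].sum()
        sig["relative_contribution_pct"] = 100.0 * sig["global_mean_shap"] / total
        sig["cumulative_contribution_pct"] = sig["relative_contribution_pct"].cumsum()
        sig.insert(0, "rank", np.arange(1, len(sig) + 1))
        table = sig
    return ShapSummary(
        table=table, all_features=allf, test_aurocs=trained.test_aurocs
    )
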