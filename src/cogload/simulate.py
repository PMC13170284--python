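"""Synthetic cohort, audit-log, and outcome generator.

No audit-log data are publicly deposited for this kind of study, so every
downstream stage (sessionization, metrics, eligibility, regression, SHAP
attribution) is exercised against simulated data whose statistical
structure matches what those stages assume:

* multi-segment provider sessions per encounter (pre-visit chart review,
  the visit itself, and optionally after-hours documentation), separated
  by idle gaps exceeding the inactivity timeout;
* an opaque event vocabulary (~215 types) with looping/revisit behaviour
  generated by a first-order "new type vs revisit" mechanism;
* one to three providers contributing events under the same encounter;
* heavy-tailed (log-normal) per-event dwell times;
* a statin-initiation outcome drawn from a logistic model quadratic in
  loop count and distinct-event count, with provider random intercepts
  playing the role of provider fixed effects.

Every generator records the ground truth it implies (true metrics, true
linear predictor, true initiation probability) so that the metric engine
and the regression stage can be tested for exact recovery.  Ground-truth
metrics are computed by independent bookkeeping during generation, not by
running the metric engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .config import (
    PROVIDER_TYPES,
    RACE_LEVELS,
    OutcomeCoefficients,
    SimulationConfig,
)
from .errors import ConfigurationError, SpecificationError

_EPOCH = pd.Timestamp("2024-01-02 08:00:00")

#: age law: normal(60.8, 11) truncated to the study's 20-75 window,
#: giving mean ~58.7 and median ~61
_AGE_LOC, _AGE_SCALE, _AGE_LO, _AGE_HI = 60.8, 11.0, 20.0, 75.0

_RACE_PROBS = (0.539, 0.124, 0.141, 0.077, 0.119)
_COMMERCIAL_PROB = 0.794

PATIENT_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "race_ethnicity",
    "insurance_class",
    "n_active_diagnoses",
    "elixhauser",
    "total_cholesterol",
    "hdl",
    "ldl",
    "hba1c",
    "systolic_bp",
    "bp_treated",
    "smoking_flag",
    "diabetes_dx_flag",
    "prior_ascvd_flag",
    "pregnancy_flag",
    "statin_allergy_flag",
    "hepatitis_flag",
    "cirrhosis_flag",
    "esrd_flag",
    "ckd_flag",
    "encounter_date",
    "lipid_days_since",
    "hba1c_days_since",
    "bp_days_since",
    "smoking_days_since",
]


def event_vocabulary(size: int) -> list:
    """Opaque event-type names EV000, EV001, ... (vendor-agnostic)."""
    if size <= 0:
        raise ConfigurationError("event_vocabulary_size must be positive")
    return [f"EV{i:03d}" for i in range(size)]


def simulate_patients(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Draw one row per patient with demographics, labs and flag columns.

    Marginals broadly emulate a statin-eligible primary-care cohort
    (mean age ~58.8, half male, ~80% commercially insured, ~6 active
    diagnoses); they are deterministic under ``config.seed``.
    """
    rng = config.rng(salt=1) if rng is None else rng
    n = config.n_patients
    if n == 0:
        return pd.DataFrame(columns=PATIENT_COLUMNS)
    a = (_AGE_LO - _AGE_LOC) / _AGE_SCALE
    b = (_AGE_HI - _AGE_LOC) / _AGE_SCALE
    age = truncnorm.rvs(a, b, loc=_AGE_LOC, scale=_AGE_SCALE, size=n, random_state=rng)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    race = rng.choice(RACE_LEVELS, size=n, p=_RACE_PROBS)
    insurance = np.where(
        rng.random(n) < _COMMERCIAL_PROB, "commercial", "non-commercial"
    )
    n_dx = 1 + rng.poisson(5.2, n)
    elix = np.round(rng.normal(1.55, 5.4, n)).astype(int)
    tc = np.clip(rng.normal(200.0, 35.0, n), 90.0, 400.0)
    hdl = np.clip(rng.normal(52.0, 14.0, n), 20.0, 120.0)
    ldl = np.clip(rng.normal(120.0, 32.0, n), 30.0, 300.0)
    diabetic_lab = rng.random(n) < 0.15
    hba1c = np.where(
        diabetic_lab,
        np.clip(rng.normal(7.4, 1.0, n), 6.5, 13.0),
        np.clip(rng.normal(5.5, 0.4, n), 4.0, 6.4),
    )
    sbp = np.clip(rng.normal(128.0, 15.0, n), 85.0, 220.0)
    female = sex == "female"
    frame = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "age": age,
            "sex": sex,
            "race_ethnicity": race,
            "insurance_class": insurance,
            "n_active_diagnoses": n_dx,
            "elixhauser": elix,
            "total_cholesterol": tc,
            "hdl": hdl,
            "ldl": ldl,
            "hba1c": hba1c,
            "systolic_bp": sbp,
            "bp_treated": rng.random(n) < 0.25,
            "smoking_flag": rng.random(n) < 0.15,
            "diabetes_dx_flag": rng.random(n) < 0.18,
            "prior_ascvd_flag": rng.random(n) < 0.12,
            "pregnancy_flag": female & (age < 50) & (rng.random(n) < 0.02),
            "statin_allergy_flag": rng.random(n) < 0.03,
            "hepatitis_flag": rng.random(n) < 0.02,
            "cirrhosis_flag": rng.random(n) < 0.01,
            "esrd_flag": rng.random(n) < 0.005,
            "ckd_flag": rng.random(n) < 0.05,
            "encounter_date": _EPOCH.normalize()
            + pd.to_timedelta(rng.integers(0, 364, n), unit="D"),
            # most recent measurement ages; a few percent fall outside the
            # 3-year lookback to exercise the missing-risk-input rule
            "lipid_days_since": rng.integers(0, 1200, n),
            "hba1c_days_since": rng.integers(0, 1200, n),
            "bp_days_since": rng.integers(0, 400, n),
            "smoking_days_since": rng.integers(0, 1095, n),
        },
        columns=PATIENT_COLUMNS,
    )
    return frame


@dataclass(frozen=True)
class EncounterSpec:
    """What to simulate for one encounter: who works on it, and when."""

    csn: object
    provider_ids: tuple
    start_time: pd.Timestamp = _EPOCH

    def __post_init__(self):
        if len(self.provider_ids) == 0:
            raise ConfigurationError("encounter spec must name at least one provider")


def _draw_merged_count(config, rng, size=None):
    m = np.rint(
        rng.lognormal(np.log(config.merged_events_median), config.merged_events_sigma, size)
    )
    return np.maximum(m, 2).astype(int)


def _draw_new_prob(config, rng, size=None):
    p = config.new_event_prob
    if p in (0.0, 1.0):  # degenerate: no between-encounter heterogeneity
        return np.full(size, p) if size is not None else np.float64(p)
    c = config.new_event_concentration
    return rng.beta(p * c, (1 - p) * c, size)


def _merged_type_sequence(m, p_new, vocab, rng):
    """First-order revisit process: each step opens a new type with
    probability ``p_new`` (while unseen types remain), otherwise revisits
    a previously seen type other than the current one."""
    V = len(vocab)
    if V == 1:
        return [vocab[0]][: max(1, 0) or 1]
    seq = []
    seen = []
    seen_set = set()
    u = rng.random(m)
    for j in range(m):
        unseen_left = len(seen) < V
        if j == 0 or (unseen_left and u[j] < p_new) or len(seen) == 1:
            while True:
                t = vocab[int(rng.integers(V))]
                if t not in seen_set:
                    break
            seen.append(t)
            seen_set.add(t)
        else:
            prev = seq[-1]
            while True:
                t = seen[int(rng.integers(len(seen)))]
                if t != prev:
                    break
        seq.append(t)
    return seq


def _generate_provider_stream(csn, provider_id, start_s, config, rng):
    """Generate one provider's raw event rows for one encounter.

    Returns (rows, ground_truth dict, segments, end_s) where ``rows`` are
    (epoch_seconds, event_type) pairs, ``segments`` is a list of
    (start_s, end_s) active segments, and ground-truth metrics come from
    generation-time bookkeeping only.
    """
    timeout = config.timeout_seconds
    vocab = event_vocabulary(config.event_vocabulary_size)
    if len(vocab) == 1:
        m = 1
    else:
        m = int(_draw_merged_count(config, rng))
    p_new = float(_draw_new_prob(config, rng))
    types = _merged_type_sequence(m, p_new, vocab, rng)
    m = len(types)

    after_hours = rng.random() < config.after_hours_prob
    n_seg = min(2 + int(after_hours), m)
    if n_seg > 1:
        cuts = np.sort(rng.choice(np.arange(1, m), size=n_seg - 1, replace=False))
    else:
        cuts = np.array([], dtype=int)
    seg_start_pos = np.concatenate([[0], cuts])
    seg_final_pos = np.concatenate([cuts - 1, [m - 1]])
    is_final = np.zeros(m, dtype=bool)
    is_final[seg_final_pos] = True

    pace = float(np.exp(rng.normal(0.0, config.dwell_scale_sigma)))
    # quantize to milliseconds so ground-truth bookkeeping and timestamp
    # arithmetic downstream are exact in double precision
    dwell = np.round(
        np.clip(pace * config.dwell_time_law.sample(rng, m), 0.5, timeout - 1.0), 3
    )
    active = np.where(is_final, timeout, dwell)

    rows = []
    segments = []
    t = round(float(start_s), 3)
    seg_open = t
    for j in range(m):
        rows.append((t, types[j]))
        if (
            not is_final[j]
            and active[j] >= 1.0
            and rng.random() < config.split_prob
        ):
            # log the same open screen as two raw rows; the metric engine
            # must merge them back into one event
            g1 = round(active[j] * rng.uniform(0.2, 0.8), 3)
            if 0.0 < g1 < active[j]:
                rows.append((t + g1, types[j]))
        if is_final[j]:
            segments.append((seg_open, t + timeout))
            idle = round(timeout + float(config.gap_time_law.sample(rng, 1)[0]), 3)
            if after_hours and n_seg >= 2 and j == seg_final_pos[-2]:
                idle += 5 * 3600.0  # documentation resumes after hours
            t = round(t + idle, 3)
            seg_open = t
        else:
            t = round(t + active[j], 3)

    total_active = float(dwell[~is_final].sum() + n_seg * timeout)
    distinct = len(set(types))
    gt = {
        "csn": csn,
        "provider_id": provider_id,
        "n_merged_events": m,
        "loops": m - distinct,
        "distinct_events": distinct,
        "total_active_seconds": total_active,
        "duration_minutes": total_active / 60.0,
        "avg_event_seconds": total_active / m,
        "n_segments": n_seg,
    }
    end_s = segments[-1][1]
    return rows, gt, segments, end_s


def simulate_audit_log(spec: EncounterSpec, config: SimulationConfig, rng=None):
    """Simulate one encounter's raw audit-log events and ground truth.

    Returns
    -------
    (audit_log, ground_truth) : (DataFrame, DataFrame)
        ``audit_log`` has one row per raw event (columns ``provider_id``,
        ``csn``, ``event_type``, ``timestamp``), chronologically ordered
        per provider; ``ground_truth`` has one row per provider with the
        metrics the metric engine must recover.
    """
    rng = config.rng(salt=2) if rng is None else rng
    start_s = pd.Timestamp(spec.start_time).value / 1e9
    all_rows, gts = [], []
    for k, pid in enumerate(spec.provider_ids):
        rows, gt, segments, _ = _generate_provider_stream(
            spec.csn, pid, start_s + 120.0 * k, config, rng
        )
        gt["segments"] = segments
        gts.append(gt)
        all_rows.extend((t, e, pid) for t, e in rows)
    audit = pd.DataFrame(
        {
            "provider_id": [r[2] for r in all_rows],
            "csn": spec.csn,
            "event_type": [r[1] for r in all_rows],
            "timestamp": _epoch_to_timestamps([r[0] for r in all_rows]),
        }
    ).sort_values("timestamp", kind="stable").reset_index(drop=True)
    return audit, pd.DataFrame(gts)


def simulate_metrics(
    config: SimulationConfig, n_encounters: int | None = None, rng=None
) -> pd.DataFrame:
    """Fast vectorized sampler of provider-encounter metric rows.

    Draws loop counts, distinct-event counts, durations and dwell
    averages from the same configured laws as the event-level generator,
    without materialising audit-log streams; used for the regression
    Monte-Carlo studies where tens of thousands of encounters are needed.
    Multi-provider encounters are expanded to one row per provider.
    """
    rng = config.rng(salt=3) if rng is None else rng
    n_enc = config.n_patients if n_encounters is None else int(n_encounters)
    patients = simulate_patients(
        SimulationConfig(
            n_patients=n_enc,
            n_providers=config.n_providers,
            seed=config.seed,
        ),
        rng=rng,
    )
    n_prov = rng.choice([1, 2, 3], size=n_enc, p=config.multi_provider_probs)
    enc_idx = np.repeat(np.arange(n_enc), n_prov)
    n_rows = len(enc_idx)
    provider_id = rng.integers(0, config.n_providers, n_rows)

    m = _draw_merged_count(config, rng, n_rows)
    p_new = _draw_new_prob(config, rng, n_rows)
    distinct = 1 + rng.binomial(m - 1, p_new)
    distinct = np.minimum(distinct, np.minimum(m, config.event_vocabulary_size))
    loops = m - distinct

    timeout = config.timeout_seconds
    n_seg = np.minimum(2 + (rng.random(n_rows) < config.after_hours_prob), m)
    counts = m - n_seg
    pace = np.exp(rng.normal(0.0, config.dwell_scale_sigma, n_rows))
    dwells = np.clip(
        np.repeat(pace, counts) * config.dwell_time_law.sample(rng, int(counts.sum())),
        0.5,
        timeout - 1.0,
    )
    cs = np.concatenate([[0.0], np.cumsum(dwells)])
    ends = np.cumsum(counts)
    starts = ends - counts
    total_active = (cs[ends] - cs[starts]) + n_seg * timeout

    out = patients.iloc[enc_idx].reset_index(drop=True)
    out.insert(0, "csn", enc_idx)
    out["provider_id"] = provider_id
    out["loops"] = loops
    out["distinct_events"] = distinct
    out["total_active_seconds"] = total_active
    out["duration_minutes"] = total_active / 60.0
    out["avg_event_seconds"] = total_active / m
    out["n_merged_events"] = m
    return out


_COVARIATE_REQUIRED = [
    "age",
    "sex",
    "race_ethnicity",
    "insurance_class",
    "n_active_diagnoses",
    "elixhauser",
    "provider_id",
]


def linear_predictor(
    frame: pd.DataFrame,
    coef: OutcomeCoefficients,
    provider_effects: pd.Series | None = None,
) -> np.ndarray:
    """Evaluate the quadratic logistic linear predictor row-wise."""
    for name, col, _ in coef.TERMS:
        if col not in frame.columns:
            raise SpecificationError(
                f"model term {name!r} requires column {col!r}, which is missing"
            )
    for col in ("sex", "race_ethnicity", "insurance_class"):
        if col not in frame.columns:
            raise SpecificationError(f"required covariate column {col!r} is missing")
    lp = np.full(len(frame), coef.intercept, dtype=float)
    for name, col, power in coef.TERMS:
        lp += getattr(coef, name) * frame[col].to_numpy(dtype=float) ** power
    race = frame["race_ethnicity"].to_numpy()
    lp += np.where(race == "Black", coef.race_black, 0.0)
    lp += np.where(race == "Hispanic", coef.race_hispanic, 0.0)
    lp += np.where(race == "Asian", coef.race_asian, 0.0)
    lp += np.where(race == "Other", coef.race_other, 0.0)
    lp += np.where(frame["sex"].to_numpy() == "female", coef.female, 0.0)
    lp += np.where(
        frame["insurance_class"].to_numpy() == "non-commercial",
        coef.non_commercial,
        0.0,
    )
    if provider_effects is not None:
        lp += (
            frame["provider_id"].map(provider_effects).fillna(0.0).to_numpy(dtype=float)
        )
    return lp


def simulate_outcomes(
    frame: pd.DataFrame,
    coefficients: OutcomeCoefficients | None = None,
    rng=None,
    provider_effects: pd.Series | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw initiation outcomes from the quadratic logistic model.

    Each row of ``frame`` (one provider-encounter, carrying the four
    metrics and patient covariates) receives an independent Bernoulli
    outcome at probability ``logistic(linear predictor)``.  Initiated
    rows get an order time placed uniformly within the row's total active
    time (recorded as an offset in seconds).

    Returns a copy of ``frame`` with ``linear_predictor``,
    ``probability``, ``outcome`` and ``order_offset_seconds`` columns.
    """
    coef = coefficients or OutcomeCoefficients()
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    if provider_effects is None and coef.provider_effect_sd > 0:
        pids = pd.unique(frame["provider_id"])
        provider_effects = pd.Series(
            rng.normal(0.0, coef.provider_effect_sd, len(pids)), index=pids
        )
    lp = linear_predictor(frame, coef, provider_effects)
    prob = expit(lp)
    outcome = rng.random(len(frame)) < prob
    offset = np.where(
        outcome,
        rng.random(len(frame)) * frame["total_active_seconds"].to_numpy(dtype=float),
        np.nan,
    )
    out = frame.copy()
    out["linear_predictor"] = lp
    out["probability"] = prob
    out["outcome"] = outcome.astype(int)
    out["order_offset_seconds"] = offset
    return out


def _epoch_to_timestamps(seconds):
    """Exact float-epoch-seconds (ms-quantized) -> datetime64[ns] conversion."""
    ms = np.round(np.asarray(seconds, dtype=float) * 1000.0).astype("int64")
    return pd.to_datetime(ms * 1_000_000)


def _offset_to_time(segments, offset):
    """Map an offset into cumulative active time to an absolute epoch-second."""
    acc = 0.0
    for start, end in segments:
        length = end - start
        if offset <= acc + length:
            return start + (offset - acc)
        acc += length
    return segments[-1][1]


@dataclass
class StudyData:
    """A full simulated study: cohort, audit log, outcomes, ground truth."""

    config: SimulationConfig
    patients: pd.DataFrame
    providers: pd.DataFrame
    encounters: pd.DataFrame
    audit_log: pd.DataFrame
    ground_truth: pd.DataFrame
    orders: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_study(config: SimulationConfig) -> StudyData:
    """Generate a complete linked dataset under one seed.

    One encounter per patient; each encounter is worked on by one to
    three providers, each contributing their own multi-segment session.
    Outcomes follow the configured quadratic logistic model; initiated
    provider-encounter rows receive a statin order timestamp placed
    uniformly within that provider's active time.
    """
    rng = config.rng(salt=4)
    patients = simulate_patients(config, rng=config.rng(salt=1))
    n_enc = config.n_patients
    providers = pd.DataFrame(
        {
            "provider_id": np.arange(config.n_providers),
            "provider_type": rng.choice(
                PROVIDER_TYPES, size=config.n_providers, p=config.provider_type_probs
            ),
            "provider_effect": rng.normal(
                0.0, config.outcome_coefficients.provider_effect_sd, config.n_providers
            ),
        }
    )
    n_prov_enc = rng.choice([1, 2, 3], size=n_enc, p=config.multi_provider_probs)

    base_s = _EPOCH.value / 1e9
    cursors = base_s + 300.0 * np.arange(config.n_providers, dtype=float)
    all_rows = []
    gts = []
    segment_map = {}
    for i in range(n_enc):
        csn = int(1_000_000 + i)
        k = int(n_prov_enc[i])
        pids = rng.choice(config.n_providers, size=k, replace=False)
        for pid in pids:
            pid = int(pid)
            rows, gt, segments, end_s = _generate_provider_stream(
                csn, pid, cursors[pid], config, rng
            )
            cursors[pid] = end_s + float(config.gap_time_law.sample(rng, 1)[0])
            all_rows.extend((t, e, pid, csn) for t, e in rows)
            gt["patient_id"] = i
            gt["segments"] = segments
            gts.append(gt)
            segment_map[(pid, csn)] = segments

    audit_log = pd.DataFrame(
        {
            "provider_id": np.array([r[2] for r in all_rows]),
            "csn": np.array([r[3] for r in all_rows]),
            "event_type": [r[1] for r in all_rows],
            "timestamp": _epoch_to_timestamps([r[0] for r in all_rows]),
        }
    ).sort_values("timestamp", kind="stable").reset_index(drop=True)

    ground_truth = pd.DataFrame(gts)
    if not ground_truth.empty:
        merged = ground_truth.merge(patients, on="patient_id", how="left")
        effects = providers.set_index("provider_id")["provider_effect"]
        ground_truth = simulate_outcomes(
            merged,
            config.outcome_coefficients,
            rng=rng,
            provider_effects=effects,
        )
        order_time = []
        for _, row in ground_truth.iterrows():
            if row["outcome"] == 1:
                secs = _offset_to_time(
                    segment_map[(row["provider_id"], row["csn"])],
                    float(row["order_offset_seconds"]),
                )
                order_time.append(_epoch_to_timestamps([secs])[0])
            else:
                order_time.append(pd.NaT)
        ground_truth["order_time"] = order_time

    initiated = ground_truth[ground_truth["outcome"] == 1] if len(ground_truth) else ground_truth
    orders = pd.DataFrame(
        {
            "csn": initiated["csn"].to_numpy() if len(initiated) else [],
            "medication": "atorvastatin",
            "order_time": initiated["order_time"].to_numpy() if len(initiated) else [],
        }
    )
    enc_outcome = (
        ground_truth.groupby("csn")
        .agg(
            patient_id=("patient_id", "first"),
            initiated=("outcome", "max"),
            order_time=("order_time", "min"),
            n_providers=("provider_id", "nunique"),
        )
        .reset_index()
        if len(ground_truth)
        else pd.DataFrame(columns=["csn", "patient_id", "initiated", "order_time", "n_providers"])
    )
    return StudyData(
        config=config,
        patients=patients,
        providers=providers,
        encounters=enc_outcome,
        audit_log=audit_log,
        ground_truth=ground_truth,
        orders=orders,
    )
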