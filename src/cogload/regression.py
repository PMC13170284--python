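"""Quadratic fixed-effects logistic regression of statin initiation.

The unit of analysis is the provider-encounter pair.  The model is a
maximum-likelihood logistic regression of the initiation indicator on
the four cognitive-load metrics — with quadratic terms for loop count
and distinct-event count by default — plus patient covariates (sex,
race/ethnicity, insurance class, comorbidity index, active-diagnosis
count, age), provider fixed effects entered as explicit indicator
columns, and sandwich standard errors clustered on the encounter.

Because a metric's quadratic contribution to the linear predictor is
b1*x + b2*x^2, its vertex -b1/(2*b2) marks where the association between
the metric and the predicted probability changes direction (the
"inflection point" on the probability scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .config import RACE_LEVELS
from .errors import SpecificationError
from .metrics import METRIC_COLUMNS

DEFAULT_QUADRATIC = {
    "loops": True,
    "distinct_events": True,
    "duration_minutes": False,
    "avg_event_seconds": False,
}


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what.

    ``metric_quadratic`` switches the quadratic term per metric (a
    quadratic always implies the linear term).  Reference levels are
    male sex, non-Hispanic/Latinx White race, commercial insurance, and
    the first provider.  Quadratics enter on the raw (uncentered) metric
    scale so that -b1/(2*b2) is directly interpretable in metric units;
    set ``center_metrics`` to fit on centered metrics instead.
    """

    outcome: str = "outcome"
    metrics: tuple = tuple(METRIC_COLUMNS)
    metric_quadratic: dict = field(default_factory=lambda: dict(DEFAULT_QUADRATIC))
    covariates: tuple = ("age", "n_active_diagnoses", "elixhauser")
    categorical: tuple = ("sex", "race_ethnicity", "insurance_class")
    fixed_effects: str = "provider_id"
    cluster_var: str = "csn"
    center_metrics: bool = False

    def quadratic_terms(self) -> list:
        return [f"{m}_sq" for m in self.metrics if self.metric_quadratic.get(m, False)]

    def without_quadratics(self) -> "ModelSpec":
        return ModelSpec(
            outcome=self.outcome,
            metrics=self.metrics,
            metric_quadratic={m: False for m in self.metrics},
            covariates=self.covariates,
            categorical=self.categorical,
            fixed_effects=self.fixed_effects,
            cluster_var=self.cluster_var,
            center_metrics=self.center_metrics,
        )


@dataclass
class RegressionResult:
    """Fit artefacts: clustered inference, fit quality, curvature summary."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    n_obs: int
    auroc: float
    spec: ModelSpec
    sm_result: object
    design: pd.DataFrame
    outcome: pd.Series
    row_index: pd.Index
    dropped_providers: list = field(default_factory=list)
    n_dropped_obs: int = 0
    metric_centers: dict = field(default_factory=dict)

    def inflection_points(self) -> dict:
        """Vertex -b1/(2*b2) per metric with an active quadratic term."""
        out = {}
        for m in self.spec.metrics:
            sq = f"{m}_sq"
            if sq in self.params.index and self.params[sq] != 0:
                out[m] = inflection_point(self.params[m], self.params[sq]) + self.metric_centers.get(m, 0.0)
        return out

    def summary_frame(self) -> pd.DataFrame:
        keep = [i for i in self.params.index if not i.startswith("fe_")]
        return pd.DataFrame(
            {
                "coefficient": self.params[keep],
                "std_err": self.bse[keep],
                "statistic": self.zvalues[keep],
                "p_value": self.pvalues[keep],
            }
        )


def _check_columns(data: pd.DataFrame, spec: ModelSpec):
    needed = (
        [spec.outcome, spec.fixed_effects, spec.cluster_var]
        + list(spec.metrics)
        + list(spec.covariates)
        + list(spec.categorical)
    )
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise SpecificationError(f"data is missing model columns {missing}")


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Assemble the design matrix (metrics, covariates, FE dummies).

    Returns (y, X, cluster_codes, centers).  Providers whose outcome does
    not vary are dropped beforehand by :func:`fit_model`; this function
    only checks the design for exact collinearity and names offenders.
    """
    _check_columns(data, spec)
    y = data[spec.outcome].astype(int)
    if not y.isin([0, 1]).all():
        raise SpecificationError(f"outcome {spec.outcome!r} must be binary 0/1")
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    centers = {}
    for m in spec.metrics:
        vals = data[m].astype(float)
        c = float(vals.mean()) if spec.center_metrics else 0.0
        centers[m] = c
        X[m] = vals - c
        if spec.metric_quadratic.get(m, False):
            X[f"{m}_sq"] = (vals - c) ** 2
    for c in spec.covariates:
        X[c] = data[c].astype(float)
    if "sex" in spec.categorical:
        X["sex_female"] = (data["sex"] == "female").astype(float)
    if "race_ethnicity" in spec.categorical:
        for level in RACE_LEVELS[1:]:
            X[f"race_{level}"] = (data["race_ethnicity"] == level).astype(float)
    if "insurance_class" in spec.categorical:
        X["insurance_non_commercial"] = (
            data["insurance_class"] == "non-commercial"
        ).astype(float)
    fe_levels = pd.unique(data[spec.fixed_effects])
    for level in fe_levels[1:]:  # first level is the reference
        X[f"fe_{level}"] = (data[spec.fixed_effects] == level).astype(float)

    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        _, rmat = np.linalg.qr(arr)
        diag = np.abs(np.diag(rmat))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise SpecificationError(f"singular design; collinear columns: {bad or 'unknown'}")
    groups = pd.Categorical(data[spec.cluster_var]).codes
    return y, X, groups, centers


def fit_model(data: pd.DataFrame, spec: ModelSpec | None = None) -> RegressionResult:
    """Fit the fixed-effects logistic model with encounter-clustered SEs.

    Providers whose outcome does not vary (all initiated or none) are
    perfectly predicted by their own indicator; their observations are
    dropped with a logged count — the standard incidental-parameter
    handling.  The in-sample AUROC of the fitted probabilities is
    reported as the fit statistic.
    """
    spec = spec or ModelSpec()
    _check_columns(data, spec)
    var = data.groupby(spec.fixed_effects)[spec.outcome].nunique()
    bad_providers = var[var < 2].index.tolist()
    kept = data[~data[spec.fixed_effects].isin(bad_providers)]
    n_dropped = len(data) - len(kept)
    if bad_providers:
        warnings.warn(
            f"dropped {n_dropped} observations from {len(bad_providers)} providers "
            "with no outcome variation"
        )
    if kept.empty:
        raise SpecificationError("no observations left after dropping non-varying providers")
    y, X, groups, centers = build_design(kept, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y.to_numpy(), X)
        res = model.fit(
            disp=0,
            method="newton",
            maxiter=200,
            cov_type="cluster",
            cov_kwds={"groups": groups},
        )
    prob = np.asarray(res.predict())
    auroc = float(roc_auc_score(y.to_numpy(), prob))
    return RegressionResult(
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(res.bse, index=X.columns),
        zvalues=pd.Series(res.tvalues, index=X.columns),
        pvalues=pd.Series(res.pvalues, index=X.columns),
        n_obs=int(len(y)),
        auroc=auroc,
        spec=spec,
        sm_result=res,
        design=X,
        outcome=y,
        row_index=kept.index,
        dropped_providers=bad_providers,
        n_dropped_obs=n_dropped,
        metric_centers=centers,
    )


@dataclass(frozen=True)
class WaldComparison:
    statistic: float
    df: int
    p_value: float
    recommendation: str  # "keep_quadratic" | "drop_quadratic"


def wald_compare(
    fit_linear: RegressionResult, fit_quadratic: RegressionResult, alpha: float = 0.05
) -> WaldComparison:
    """Joint Wald test of the quadratic terms, using the clustered covariance.

    The linear specification must nest inside the quadratic one; the test
    is evaluated on the quadratic fit.  Recommends keeping the quadratic
    terms when p < alpha.
    """
    lin_cols = set(fit_linear.params.index)
    quad_cols = set(fit_quadratic.params.index)
    extra = sorted(quad_cols - lin_cols)
    if not lin_cols <= quad_cols or not extra:
        raise SpecificationError("linear spec does not nest inside the quadratic spec")
    if any(not c.endswith("_sq") for c in extra):
        raise SpecificationError(f"non-quadratic extra terms {extra}; specs are not nested")
    constraint = ", ".join(f"{c} = 0" for c in extra)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        test = fit_quadratic.sm_result.wald_test(constraint, scalar=True, use_f=False)
    stat = float(test.statistic)
    df = len(extra)
    p = float(test.pvalue)
    return WaldComparison(
        statistic=stat,
        df=df,
        p_value=p,
        recommendation="keep_quadratic" if p < alpha else "drop_quadratic",
    )


def inflection_point(beta_linear: float, beta_quadratic: float) -> float:
    """Vertex of b1*x + b2*x^2: the metric value -b1/(2*b2)."""
    if beta_quadratic == 0:
        raise SpecificationError("vertex undefined: quadratic coefficient is zero")
    return -beta_linear / (2.0 * beta_quadratic)


def average_marginal_effects(
    result: RegressionResult,
    metric: str,
    grid=None,
    n_grid: int = 50,
    step: float | None = None,
) -> pd.DataFrame:
    """Average marginal effect of one metric over a grid of its values.

    For each grid value g, every observation's metric is set to g (other
    columns at observed values), and the AME is the sample mean of the
    central finite-difference derivative of the predicted probability.
    The averaged predicted-probability curve is returned alongside, for
    predicted-probability plots.
    """
    if metric not in result.spec.metrics:
        raise SpecificationError(f"{metric!r} is not a model metric")
    X = result.design
    obs = X[metric].to_numpy() + result.metric_centers.get(metric, 0.0)
    lo, hi = float(np.min(obs)), float(np.max(obs))
    if grid is None:
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    if (grid < lo).any() or (grid > hi).any():
        warnings.warn("grid extends outside the observed metric range; extrapolating")
    if step is None:
        step = max(1e-4, 1e-4 * (hi - lo))
    beta = result.params.to_numpy()
    cols = list(result.params.index)
    j = cols.index(metric)
    jsq = cols.index(f"{metric}_sq") if f"{metric}_sq" in cols else None
    base = X.to_numpy(dtype=float).copy()
    center = result.metric_centers.get(metric, 0.0)

    def mean_prob(g):
        base[:, j] = g - center
        if jsq is not None:
            base[:, jsq] = (g - center) ** 2
        return float(np.mean(expit(base @ beta)))

    rows = []
    for g in grid:
        p_mid = mean_prob(g)
        ame = (mean_prob(g + step) - mean_prob(g - step)) / (2.0 * step)
        rows.append({"grid": float(g), "mean_probability": p_mid, "ame": ame})
    return pd.DataFrame(rows)


@dataclass
class TrimSensitivity:
    fits: dict  # metric -> RegressionResult (or exception message string)
    stability: pd.DataFrame


def trim_mask(values, trim_fraction: float) -> np.ndarray:
    """Boolean mask keeping values inside the [q, 1-q] quantile band.

    Rows strictly below the ``trim_fraction`` quantile or strictly above
    the ``1 - trim_fraction`` quantile are dropped (type-7 quantiles), so
    on 100 distinct values a 1% trim removes exactly the min and the max.
    """
    vals = np.asarray(values, dtype=float)
    lo = np.quantile(vals, trim_fraction)
    hi = np.quantile(vals, 1.0 - trim_fraction)
    return (vals >= lo) & (vals <= hi)


def trim_sensitivity(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    trim_fraction: float = 0.01,
    full_fit: RegressionResult | None = None,
) -> TrimSensitivity:
    """Refit after trimming the tails of each cognitive-load metric.

    One refit per metric: rows strictly below that metric's
    ``trim_fraction`` quantile or strictly above its ``1-trim_fraction``
    quantile are dropped and the same model refitted.  The stability
    table compares sign and significance (at 0.05) of every metric term
    against the untrimmed fit.
    """
    spec = spec or ModelSpec()
    full = full_fit or fit_model(data, spec)
    metric_terms = [c for c in full.params.index if c in spec.metrics or c.endswith("_sq")]
    fits, rows = {}, []
    for m in spec.metrics:
        kept = data[trim_mask(data[m], trim_fraction)]
        try:
            refit = fit_model(kept, spec)
        except Exception as exc:  # degenerate post-trim design: report, continue
            fits[m] = f"failed: {exc}"
            continue
        fits[m] = refit
        for term in metric_terms:
            if term not in refit.params.index:
                continue
            sign_full = np.sign(full.params[term])
            sig_full = full.pvalues[term] < 0.05
            sign_trim = np.sign(refit.params[term])
            sig_trim = refit.pvalues[term] < 0.05
            rows.append(
                {
                    "trimmed_metric": m,
                    "term": term,
                    "sign_full": sign_full,
                    "sign_trimmed": sign_trim,
                    "significant_full": sig_full,
                    "significant_trimmed": sig_trim,
                    "stable": (sign_full == sign_trim) and (sig_full == sig_trim),
                }
            )
    return TrimSensitivity(fits=fits, stability=pd.DataFrame(rows))
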