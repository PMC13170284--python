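"""Tukey-IQR outlier flagging and descriptive group comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_COLUMNS


@dataclass
class OutlierFlags:
    """Per-encounter Tukey flags and the fences that produced them.

    ``flags`` has one boolean column per metric; ``any_outlier`` is their
    row-wise OR; ``fences`` maps metric -> (lower, upper) where
    lower = Q1 - 1.5*IQR and upper = Q3 + 1.5*IQR, quartiles by linear
    interpolation (type 7).
    """

    flags: pd.DataFrame
    any_outlier: pd.Series
    fences: dict


def tukey_flags(table: pd.DataFrame, metrics=None, k: float = 1.5) -> OutlierFlags:
    """Flag records whose metric values fall outside the Tukey fences.

    Fences are computed per metric over the full sample; a record is an
    outlier if *any* metric exceeds its fences.  A metric with zero IQR
    (constant to the quartiles) produces no flags and a warning.
    """
    metrics = list(metrics) if metrics is not None else [
        c for c in METRIC_COLUMNS if c in table.columns
    ]
    flags = pd.DataFrame(index=table.index)
    fences = {}
    for m in metrics:
        vals = table[m].astype(float)
        ok = vals.dropna()
        if len(ok) < 4:
            raise ValueError(f"metric {m!r} needs >=4 non-missing values")
        q1, q3 = np.percentile(ok, [25, 75])  # linear interpolation (type 7)
        iqr = q3 - q1
        lo, hi = q1 - k * iqr, q3 + k * iqr
        fences[m] = (float(lo), float(hi))
        if iqr == 0:
            warnings.warn(f"metric {m!r} has zero IQR; no outliers flagged")
            flags[m] = False
        else:
            flags[m] = (vals < lo) | (vals > hi)
            flags[m] = flags[m].fillna(False)
    return OutlierFlags(flags=flags, any_outlier=flags.any(axis=1), fences=fences)


@dataclass(frozen=True)
class OutlierComparison:
    table: np.ndarray  # 2x2: rows outlier yes/no, cols initiated yes/no
    chi2: float
    p_value: float
    risk_ratio: float
    rr_ci: tuple
    odds_ratio: float
    or_ci: tuple
    continuity_corrected: bool = False


def compare_outlier_groups(any_outlier, outcomes, alpha: float = 0.05) -> OutlierComparison:
    """Pearson chi-square plus RR and OR (Wald CIs) for outlier vs not.

    Rows of the 2x2 table are outlier status (yes, no), columns are
    initiation (yes, no).  A zero cell triggers the Haldane-Anscombe 0.5
    continuity correction for the estimates, flagged in the result.
    """
    flag = np.asarray(any_outlier, dtype=bool)
    y = np.asarray(outcomes, dtype=int)
    if flag.all() or (~flag).all():
        raise ValueError("both outlier groups must be non-empty")
    a = int(((flag) & (y == 1)).sum())
    b = int(((flag) & (y == 0)).sum())
    c = int(((~flag) & (y == 1)).sum())
    d = int(((~flag) & (y == 0)).sum())
    table = np.array([[a, b], [c, d]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    corrected = bool((table == 0).any())
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    rr = (a / (a + b)) / (c / (c + d))
    orr = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se_lnrr = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    se_lnor = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    rr_ci = (float(rr * np.exp(-z * se_lnrr)), float(rr * np.exp(z * se_lnrr)))
    or_ci = (float(orr * np.exp(-z * se_lnor)), float(orr * np.exp(z * se_lnor)))
    return OutlierComparison(
        table=np.array([[a, b], [c, d]], dtype=float),
        chi2=float(chi2),
        p_value=float(p),
        risk_ratio=float(rr),
        rr_ci=rr_ci,
        odds_ratio=float(orr),
        or_ci=or_ci,
        continuity_corrected=corrected,
    )


def descriptive_table(
    data: pd.DataFrame,
    by: str = "initiated",
    continuous=None,
    categorical=None,
) -> pd.DataFrame:
    """Stratified summary in the style of a cohort descriptives table.

    Continuous variables get mean (SD) and median [min, max] per stratum
    with a Welch two-sample t-test p-value; categorical variables get
    counts (%) per level with a chi-square p-value.  Empty strata are
    omitted with a warning.
    """
    continuous = list(continuous or [])
    categorical = list(categorical or [])
    groups = []
    for level, sub in data.groupby(by, sort=True, observed=False):
        if sub.empty:
            warnings.warn(f"stratum {by}={level!r} is empty; omitted")
            continue
        groups.append((level, sub))
    if len(groups) == 0:
        raise ValueError("no non-empty strata")

    rows = []
    for var in continuous:
        pval = np.nan
        if len(groups) == 2:
            x0 = groups[0][1][var].dropna()
            x1 = groups[1][1][var].dropna()
            if x0.std(ddof=1) == 0 and x1.std(ddof=1) == 0 and x0.mean() == x1.mean():
                pval = 1.0
            else:
                pval = stats.ttest_ind(x0, x1, equal_var=False).pvalue
        row = {"variable": var, "statistic": "mean_sd", "p_value": pval}
        for level, sub in groups:
            v = sub[var].astype(float)
            row[f"{by}={level}"] = f"{v.mean():.2f} ({v.std(ddof=1):.2f})" if len(v) > 1 else f"{v.mean():.2f} (--)"
        rows.append(row)
        row = {"variable": var, "statistic": "median_min_max", "p_value": np.nan}
        for level, sub in groups:
            v = sub[var].astype(float)
            row[f"{by}={level}"] = f"{v.median():.2f} [{v.min():.2f}, {v.max():.2f}]"
        rows.append(row)
    for var in categorical:
        levels = sorted(data[var].dropna().unique(), key=str)
        pval = np.nan
        if len(groups) >= 2:
            ct = pd.crosstab(data[var], data[by])
            if ct.shape[0] > 1 and (ct.to_numpy().sum(axis=0) > 0).all():
                pval = stats.chi2_contingency(ct.to_numpy())[1]
            else:
                pval = 1.0
        for i, lv in enumerate(levels):
            row = {
                "variable": var,
                "statistic": f"n_pct[{lv}]",
                "p_value": pval if i == 0 else np.nan,
            }
            for glevel, sub in groups:
                cnt = int((sub[var] == lv).sum())
                row[f"{by}={glevel}"] = f"{cnt} ({100.0 * cnt / len(sub):.1f}%)"
            rows.append(row)
    return pd.DataFrame(rows)
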