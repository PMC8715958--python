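"""Longitudinal validation of diagnoses via memory-score trajectories.

Diagnoses made from baseline PET are validated against follow-up
neuropsychological testing: a valid impaired/healthy split should show
diverging score trajectories.  Three tools implement this: 6-month binned
between-group tests with family-wise error control, ordinary
least-squares trends with 95% confidence intervals, and within-subject
score stability (the SD of a subject's repeated scores).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SCORE_COLUMNS = ("mmse_recall", "adas_recall", "cdr_memory")


class LongitudinalError(ValueError):
    pass


def bin_visits(
    visits: pd.DataFrame, interval: float = 6.0, horizon: float = 96.0
) -> pd.DataFrame:
    """Assign each visit to the nearest multiple of ``interval`` months.

    Bins are ``{interval, 2*interval, ..., horizon}``; exact midpoints go
    to the lower bin.  Visits beyond ``horizon + interval/2`` — or closer
    to month 0 than to the first bin — are dropped.
    """
    if interval <= 0:
        raise LongitudinalError("bin interval must be positive")
    months = np.asarray(visits["months"], dtype=float)
    if (months < 0).any():
        raise LongitudinalError("negative months in visit table")
    # round half down: ties go to the lower bin
    idx = np.ceil(months / interval - 0.5).astype(int)
    n_bins = int(horizon // interval)
    keep = (idx >= 1) & (idx <= n_bins)
    out = visits.loc[keep].copy()
    out["bin_months"] = idx[keep] * interval
    return out


def timepoint_tests(
    binned: pd.DataFrame,
    diagnoses: pd.Series | dict,
    test: str,
    alpha_levels=(0.001, 0.01, 0.05),
) -> pd.DataFrame:
    """Welch t-test per time bin between diagnosed-impaired and -healthy.

    ``diagnoses`` maps sample id -> "impaired"/"healthy".  P-values are
    Bonferroni-corrected over the bins actually evaluated for this score;
    bins where either group is absent are listed with ``skipped=True``.
    """
    if test not in binned.columns:
        raise LongitudinalError(f"unknown score column {test!r}")
    diag = pd.Series(diagnoses)
    groups = binned["sample_id"].map(diag)
    rows = []
    for bin_m, chunk in binned.groupby("bin_months"):
        g = groups.loc[chunk.index]
        imp = chunk.loc[g == "impaired", test].to_numpy(dtype=float)
        hea = chunk.loc[g == "healthy", test].to_numpy(dtype=float)
        if len(imp) < 2 or len(hea) < 2:
            rows.append({"bin_months": bin_m, "n_impaired": len(imp),
                         "n_healthy": len(hea), "t": np.nan, "p": np.nan,
                         "skipped": True})
            continue
        t, p = stats.ttest_ind(imp, hea, equal_var=False)
        rows.append({"bin_months": bin_m, "n_impaired": len(imp),
                     "n_healthy": len(hea), "t": float(t), "p": float(p),
                     "skipped": False})
    table = pd.DataFrame(rows)
    evaluated = int((~table["skipped"]).sum())
    if evaluated == 0:
        raise LongitudinalError("no bin with both diagnosis groups present")
    table["p_corrected"] = np.minimum(table["p"] * evaluated, 1.0)
    for a in alpha_levels:
        table[f"sig_{a}"] = table["p_corrected"] < a
    return table


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of score on months with a 95% CI on the slope."""

    slope: float
    intercept: float
    slope_ci_95: tuple[float, float]
    slope_se: float
    n: int

    @property
    def df(self) -> int:
        return self.n - 2


def fit_trend(visits: pd.DataFrame, test: str) -> TrendFit:
    """Ordinary least squares of one score on months after baseline.

    CI is ``slope +/- t(0.975, n-2) * SE``.  Requires at least 3 visits
    spanning at least 2 distinct months.
    """
    if test not in visits.columns:
        raise LongitudinalError(f"unknown score column {test!r}")
    x = np.asarray(visits["months"], dtype=float)
    y = np.asarray(visits[test], dtype=float)
    if len(x) < 3 or np.unique(x).size < 2:
        raise LongitudinalError(
            "trend fit needs >= 3 visits over >= 2 distinct months"
        )
    fit = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, len(x) - 2)
    half = tcrit * fit.stderr
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_ci_95=(float(fit.slope - half), float(fit.slope + half)),
        slope_se=float(fit.stderr),
        n=len(x),
    )


def per_sample_slopes(visits: pd.DataFrame, test: str) -> pd.Series:
    """Fitted OLS slope of one score for every sample with enough visits."""
    slopes = {}
    for sid, chunk in visits.groupby("sample_id"):
        x = chunk["months"].to_numpy(dtype=float)
        if len(x) < 3 or np.unique(x).size < 2:
            continue
        slopes[sid] = fit_trend(chunk, test).slope
    return pd.Series(slopes, name=f"{test}_slope")


def stability_sd(
    visits: pd.DataFrame, grouping: pd.Series | dict,
    tests=SCORE_COLUMNS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Within-subject longitudinal SD per score, compared between groups.

    ``grouping`` maps sample id -> group name (e.g. energetic /
    non-energetic).  Returns the per-subject SD table and a per-score
    Welch-t comparison of the two groups' SD distributions.
    """
    grouping = pd.Series(grouping)
    counts = visits.groupby("sample_id").size()
    eligible = counts.index[counts >= 2]
    if len(eligible) == 0:
        raise LongitudinalError("no subject has >= 2 visits")
    sds = (
        visits[visits["sample_id"].isin(eligible)]
        .groupby("sample_id")[list(tests)]
        .std(ddof=1)
    )
    sds["group"] = sds.index.map(grouping)
    levels = [g for g in pd.unique(sds["group"]) if pd.notna(g)]
    if len(levels) != 2:
        raise LongitudinalError(
            f"stability comparison needs exactly 2 groups, got {levels}"
        )
    rows = []
    for test in tests:
        a = sds.loc[sds["group"] == levels[0], test].dropna()
        b = sds.loc[sds["group"] == levels[1], test].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({
            "test": test, "group_a": levels[0], "group_b": levels[1],
            "mean_sd_a": float(a.mean()), "mean_sd_b": float(b.mean()),
            "t": float(t), "p": float(p),
        })
    return sds, pd.DataFrame(rows)
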