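"""Rule-based triage of memory-test batteries into certain / uncertain cases.

Three memory measures are compared per sample: the MMSE delayed word recall
(0-3 words), the ADAS-Cog delayed word recall (0-30 words, higher = better
recall in this convention), and the CDR memory box score (0, 0.5, 1, 2, 3).
A sample is *certain impaired* only when all three tests agree on
impairment, *certain healthy* only when all three agree on intact memory,
and *uncertain* otherwise.  The ADAS cut points default to the published
constants 12 and 23, which equal mean -/+ one sample standard deviation of
the ADAS recall over the cohort they were derived from;
:func:`compute_adas_thresholds` recomputes them for a new cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CERTAIN_IMPAIRED = "certain_impaired"
CERTAIN_HEALTHY = "certain_healthy"
UNCERTAIN = "uncertain"

LABELS = (CERTAIN_IMPAIRED, CERTAIN_HEALTHY, UNCERTAIN)

#: Legal CDR memory box values.
CDR_LEVELS = (0.0, 0.5, 1.0, 2.0, 3.0)

MMSE_RANGE = (0, 3)
ADAS_RANGE = (0, 30)


class TriageError(ValueError):
    """Raised for invalid scores or thresholds."""


@dataclass(frozen=True)
class TriageThresholds:
    """Cut points of the three-test concordance rule.

    ``certain_impaired`` requires ``mmse <= mmse_max_impaired``,
    ``adas < adas_low`` and ``cdr >= cdr_min_impaired``;
    ``certain_healthy`` requires ``mmse > mmse_max_impaired``,
    ``adas > adas_high`` and ``cdr == cdr_healthy``.  All inequalities are
    strict or non-strict exactly as written; boundary scores fall to
    *uncertain*.
    """

    mmse_max_impaired: float = 1.0
    adas_low: float = 12.0
    adas_high: float = 23.0
    cdr_min_impaired: float = 1.0
    cdr_healthy: float = 0.0

    def __post_init__(self) -> None:
        if not self.adas_low < self.adas_high:
            raise TriageError(
                f"adas_low ({self.adas_low}) must be < adas_high ({self.adas_high})"
            )


DEFAULT_THRESHOLDS = TriageThresholds()


def compute_adas_thresholds(
    adas_scores, rounding: str = "none"
) -> tuple[float, float]:
    """Derive (mean - SD, mean + SD) ADAS recall cut points from a cohort.

    Uses the sample standard deviation (n - 1 denominator).  With
    ``rounding="nearest-integer"`` both cut points are rounded to the
    nearest integer, which is how the published constants 12 and 23 arise.
    """
    scores = np.asarray(adas_scores, dtype=float)
    if scores.size < 2:
        raise TriageError("need at least 2 ADAS scores to derive thresholds")
    mean = scores.mean()
    sd = scores.std(ddof=1)
    low, high = mean - sd, mean + sd
    if rounding == "nearest-integer":
        low, high = round(low), round(high)
    elif rounding != "none":
        raise TriageError(f"unknown rounding mode {rounding!r}")
    return float(low), float(high)


def _validate_scores(mmse, adas, cdr) -> None:
    if not (MMSE_RANGE[0] <= mmse <= MMSE_RANGE[1]):
        raise TriageError(f"MMSE-Recall {mmse} outside {MMSE_RANGE}")
    if not (ADAS_RANGE[0] <= adas <= ADAS_RANGE[1]):
        raise TriageError(f"ADAS-Cog-Recall {adas} outside {ADAS_RANGE}")
    if cdr not in CDR_LEVELS:
        raise TriageError(f"CDR-Memory {cdr} not one of {CDR_LEVELS}")


def assign_group(
    mmse_recall: float,
    adas_recall: float,
    cdr_memory: float,
    thresholds: TriageThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Label one sample as certain_impaired / certain_healthy / uncertain."""
    _validate_scores(mmse_recall, adas_recall, cdr_memory)
    t = thresholds
    if (
        mmse_recall <= t.mmse_max_impaired
        and adas_recall < t.adas_low
        and cdr_memory >= t.cdr_min_impaired
    ):
        return CERTAIN_IMPAIRED
    if (
        mmse_recall > t.mmse_max_impaired
        and adas_recall > t.adas_high
        and cdr_memory == t.cdr_healthy
    ):
        return CERTAIN_HEALTHY
    return UNCERTAIN


def triage_cohort(
    cohort: pd.DataFrame,
    thresholds: TriageThresholds = DEFAULT_THRESHOLDS,
) -> tuple[pd.DataFrame, dict]:
    """Label every sample of a cohort table and summarise the partition.

    ``cohort`` must carry ``mmse_recall``, ``adas_recall`` and
    ``cdr_memory`` columns (and preferably an ``id`` column for error
    reporting).  Returns a labelled copy and a summary dict with per-label
    counts and the fraction of uncertain samples.
    """
    required = ["mmse_recall", "adas_recall", "cdr_memory"]
    missing_cols = [c for c in required if c not in cohort.columns]
    if missing_cols:
        raise TriageError(f"cohort lacks columns {missing_cols}")
    bad = cohort.index[cohort[required].isna().any(axis=1)]
    if len(bad):
        ids = (
            cohort.loc[bad, "id"].tolist()
            if "id" in cohort.columns
            else bad.tolist()
        )
        raise TriageError(f"samples with missing scores: {ids}")

    labelled = cohort.copy()
    labelled["triage_label"] = [
        assign_group(m, a, c, thresholds)
        for m, a, c in zip(
            cohort["mmse_recall"], cohort["adas_recall"], cohort["cdr_memory"]
        )
    ]
    counts = {lab: int((labelled["triage_label"] == lab).sum()) for lab in LABELS}
    n = len(labelled)
    summary = {
        "n": n,
        "counts": counts,
        "fraction_uncertain": counts[UNCERTAIN] / n if n else float("nan"),
    }
    return labelled, summary
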