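"""Paired epoch-comparison testing and county-level summaries.

Each community contributes one value per epoch; the test runs on the paired
differences.  Normality of the differences (Shapiro–Wilk) gates the choice
between a paired t-test and the Wilcoxon signed-rank test; homogeneity of
variances, sometimes quoted alongside, is not applicable to a paired design
and plays no role.  Wilcoxon uses the exact null for n ≤ 25 and the normal
approximation with continuity correction above.  Significance stars follow
the conventional thresholds: *** p < 0.001, ** p < 0.01, * p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

WILCOXON_EXACT_MAX_N = 25
STAR_THRESHOLDS = (0.001, 0.01, 0.05)


@dataclass
class PairedTestResult:
    test_name: str  # paired-t | wilcoxon-signed-rank | degenerate
    statistic: float
    p_value: float
    n: int
    mean_diff: float
    significance_code: str


def significance_code(p: float) -> str:
    if p < STAR_THRESHOLDS[0]:
        return "***"
    if p < STAR_THRESHOLDS[1]:
        return "**"
    if p < STAR_THRESHOLDS[2]:
        return "*"
    return "ns"


def choose_test(diffs: np.ndarray, alpha: float = 0.05) -> str:
    """Pick the paired test from the distribution of the differences.

    Shapiro–Wilk on the differences: paired t when normality is not
    rejected (p ≥ alpha), Wilcoxon signed-rank otherwise.  All-zero
    differences are degenerate (no change to test); constant non-zero
    differences fall to Wilcoxon, where the t statistic is undefined.
    """
    diffs = np.asarray(diffs, float)
    if len(diffs) < 3:
        raise ValueError("need at least 3 pairs to choose a test")
    if np.all(diffs == 0):
        return "degenerate"
    if np.ptp(diffs) == 0:
        return "wilcoxon-signed-rank"
    p_norm = stats.shapiro(diffs).pvalue
    return "paired-t" if p_norm >= alpha else "wilcoxon-signed-rank"


def paired_change_test(
    values_t0: np.ndarray,
    values_t1: np.ndarray,
    alpha: float = 0.05,
    force_test: str | None = None,
) -> PairedTestResult:
    """Two-sided paired test of t1 − t0 differences.

    ``force_test`` overrides the normality gate (used when a caller wants
    one protocol across many strata).
    """
    v0 = np.asarray(values_t0, float)
    v1 = np.asarray(values_t1, float)
    if v0.shape != v1.shape:
        raise ValueError("paired samples must have equal length")
    ok = np.isfinite(v0) & np.isfinite(v1)
    v0, v1 = v0[ok], v1[ok]
    diffs = v1 - v0
    n = len(diffs)
    if n < 3 or np.all(diffs == 0):
        return PairedTestResult(
            test_name="degenerate",
            statistic=float("nan"),
            p_value=1.0,
            n=n,
            mean_diff=float(diffs.mean()) if n else float("nan"),
            significance_code="ns",
        )
    test = force_test or choose_test(diffs, alpha)
    if test == "paired-t":
        res = stats.ttest_rel(v1, v0)
        statistic, p = float(res.statistic), float(res.pvalue)
    elif test == "wilcoxon-signed-rank":
        method = "exact" if n <= WILCOXON_EXACT_MAX_N else "approx"
        res = stats.wilcoxon(
            diffs, alternative="two-sided", method=method, correction=(method == "approx")
        )
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError(f"unknown test: {test!r}")
    return PairedTestResult(
        test_name=test,
        statistic=statistic,
        p_value=p,
        n=n,
        mean_diff=float(diffs.mean()),
        significance_code=significance_code(p),
    )


def county_summary(
    values: np.ndarray, county_labels: np.ndarray, metric: str = ""
) -> pd.DataFrame:
    """Per-county mean ± standard error (sample SD / √n).

    A county with a single observation reports SE 0 and is flagged; empty
    counties are omitted.
    """
    values = np.asarray(values, float)
    county_labels = np.asarray(county_labels)
    if values.shape != county_labels.shape:
        raise ValueError("values and county labels must have equal length")
    rows = []
    for county in sorted(pd.unique(county_labels)):
        sel = values[(county_labels == county) & np.isfinite(values)]
        n = len(sel)
        if n == 0:
            continue
        se = float(sel.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "county": county,
                "metric": metric,
                "mean": float(sel.mean()),
                "standard_error": se,
                "n": n,
                "single_observation": n == 1,
            }
        )
    return pd.DataFrame(rows)


def paired_summary_table(
    samples: list[dict],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the paired protocol over many (metric, class, scope) strata.

    Each entry: {metric, resource_class, scope, values_t0, values_t1}.
    """
    rows = []
    for s in samples:
        res = paired_change_test(s["values_t0"], s["values_t1"], alpha=alpha)
        rows.append(
            {
                "metric": s["metric"],
                "resource_class": s.get("resource_class", "all"),
                "scope": s.get("scope", "all"),
                "mean_t0": float(np.nanmean(np.asarray(s["values_t0"], float)))
                if len(s["values_t0"])
                else float("nan"),
                "mean_t1": float(np.nanmean(np.asarray(s["values_t1"], float)))
                if len(s["values_t1"])
                else float("nan"),
                "mean_diff": res.mean_diff,
                "test": res.test_name,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n": res.n,
                "stars": res.significance_code,
            }
        )
    return pd.DataFrame(rows)
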