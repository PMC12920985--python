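"""Statistical validation of metric values against ordinal quality scores.

A segmentation metric is useful insofar as it tracks expert judgement.
This module provides the machinery to test that on scored mask pairs:
Spearman rank correlation between metric values and ordinal scores,
per-score-class summaries (min/mean/max/sd), two-sided F-tests of equal
variances between metrics within a class, and Benjamini-Hochberg FDR
correction for the resulting family of p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "ClassSummary",
    "spearman",
    "f_test_variances",
    "fdr_correct",
    "class_summaries",
    "pairwise_variance_tests",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    p_value_fdr: float | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class ClassSummary:
    score_class: int
    metric: str
    n: int
    min: float
    mean: float
    max: float
    sd: float  # nan when the class has fewer than two members


def spearman(values, scores, method: str = "asymptotic") -> TestResult:
    """Tie-corrected Spearman rank correlation with a two-sided p-value.

    ``method='asymptotic'`` uses the t-approximation with n-2 degrees of
    freedom (adequate for the sample sizes these experiments use);
    ``method='exact'`` enumerates pairings and is only available for
    n <= 10.  Constant input has undefined rank correlation and raises.
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(scores, dtype=float)
    if v.shape != s.shape or v.ndim != 1:
        raise ValueError("values and scores must be 1-D sequences of equal length")
    if v.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(v) == 0 or np.ptp(s) == 0:
        raise ValueError("constant input: rank correlation is undefined")
    if method == "asymptotic":
        rho, p = sps.spearmanr(v, s)
    elif method == "exact":
        if v.size > 10:
            raise ValueError("exact method is limited to n <= 10")
        from itertools import permutations

        ra, rb = sps.rankdata(v), sps.rankdata(s)
        ra, rb = ra - ra.mean(), rb - rb.mean()
        norm = np.sqrt((ra**2).sum() * (rb**2).sum())
        rho = float((ra * rb).sum() / norm)
        hits, total = 0, 0
        for perm in permutations(range(v.size)):
            r = float((ra[list(perm)] * rb).sum() / norm)
            hits += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = hits / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return TestResult(float(rho), float(p), f"spearman-{method}")


def f_test_variances(a, b) -> TestResult:
    """Two-sided F-test of equality of variances.

    F = var(a)/var(b) with sample (n-1) variances; the two-sided p-value is
    2*min(P(F<=f), P(F>=f)) capped at 1, from the F distribution with
    (n_a-1, n_b-1) degrees of freedom.  Significance at the 5% level is
    reported as a flag.  Raises when both samples have zero variance, where
    the test is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("both samples have zero variance: F-test undefined")
    f = va / vb if vb > 0 else np.inf
    dist = sps.f(a.size - 1, b.size - 1)
    p = min(1.0, 2.0 * min(dist.cdf(f), dist.sf(f)))
    return TestResult(float(f), float(p), "f-test", significant=bool(p < SIGNIFICANCE_LEVEL))


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def class_summaries(table: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Per-class, per-metric min/mean/max/sd summaries.

    ``table`` needs a ``score`` column (integers 0-4) plus one column per
    metric.  Classes with a single member report sd as NaN; the sd uses the
    n-1 denominator.  Empty classes are simply absent from the output.
    """
    if "score" not in table.columns:
        raise ValueError("table must have a 'score' column")
    if not table["score"].isin(range(5)).all():
        raise ValueError("scores must be integers 0-4")
    if metrics is None:
        metrics = [c for c in table.columns if c != "score"]
    rows = []
    for cls, group in table.groupby("score", sort=True):
        for m in metrics:
            vals = group[m].to_numpy(dtype=float)
            rows.append(
                ClassSummary(
                    score_class=int(cls),
                    metric=m,
                    n=vals.size,
                    min=float(vals.min()),
                    mean=float(vals.mean()),
                    max=float(vals.max()),
                    sd=float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
                )
            )
    return pd.DataFrame([r.__dict__ for r in rows])


def pairwise_variance_tests(
    table: pd.DataFrame, metrics: list[str] | None = None
) -> pd.DataFrame:
    """F-tests of equal variances between every metric pair, per score class.

    Classes where a pair's test is undefined (both variances zero, as for
    the fully-wrong class where every value of a metric can be 0) are
    skipped.  All resulting p-values are FDR-corrected as one family.
    """
    if metrics is None:
        metrics = [c for c in table.columns if c != "score"]
    rows = []
    for cls, group in table.groupby("score", sort=True):
        for i, ma in enumerate(metrics):
            for mb in metrics[i + 1 :]:
                try:
                    res = f_test_variances(group[ma], group[mb])
                except ValueError:
                    continue
                rows.append(
                    {
                        "score_class": int(cls),
                        "metric_a": ma,
                        "metric_b": mb,
                        "f_statistic": res.statistic,
                        "p_value": res.p_value,
                    }
                )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_value_fdr"] = fdr_correct(out["p_value"].to_numpy())
        out["significant"] = out["p_value"] < SIGNIFICANCE_LEVEL
    return out
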