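"""Per-group summaries and nonparametric between-group comparisons.

The statistical layer mirrors the common clinical-kinematics reporting
shape: per group a sample size, mean, first/third quartiles and a t-based
95% confidence interval of the mean; between groups a Shapiro-Wilk
normality gate (logged), a Kruskal-Wallis omnibus test per parameter, and
pairwise two-sided Mann-Whitney post hoc tests run only when the omnibus
test is significant.  Quartiles use linear interpolation between order
statistics; post hoc p values are unadjusted by default with Bonferroni and
Holm adjustments available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, ValidationError
from .kinematics import PARAMETERS

DEFAULT_GROUP_ORDER = ("normal", "aspiration", "stasis")


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    q1: float
    q3: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PairwiseResult:
    u: float
    p: float
    p_adjusted: float | None
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    kruskal_wallis_h: float
    kruskal_wallis_p: float
    summaries: Mapping[str, GroupSummary]
    pairwise: Mapping[tuple[str, str], PairwiseResult] | None


def summarize_group(values: Sequence[float]) -> GroupSummary:
    """n, mean, linear-interpolation quartiles and t-based 95% CI."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise DegenerateDataError(f"need at least 2 values, got {v.size}")
    if not np.all(np.isfinite(v)):
        raise ValidationError("values must be finite")
    n = v.size
    mean = float(v.mean())
    q1, q3 = np.percentile(v, [25, 75])  # linear interpolation (default)
    sd = float(v.std(ddof=1))
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return GroupSummary(
        n=n, mean=mean, q1=float(q1), q3=float(q3),
        ci_low=mean - float(half), ci_high=mean + float(half),
    )


def normality_test(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p; constant samples are degenerate."""
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise DegenerateDataError(f"Shapiro-Wilk needs n >= 3, got {v.size}")
    if np.ptp(v) == 0:
        raise DegenerateDataError("Shapiro-Wilk is undefined for constant samples")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Mid-rank Kruskal-Wallis H with tie correction; chi-square p, k-1 df."""
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrays):
        raise ValidationError("Kruskal-Wallis groups must be non-empty")
    if sum(a.size for a in arrays) < 3:
        raise ValidationError("Kruskal-Wallis needs a total of at least 3 values")
    if np.ptp(np.concatenate(arrays)) == 0:
        raise DegenerateDataError(
            "Kruskal-Wallis degenerate: all values identical (tie correction "
            "divides by zero)"
        )
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


_EXACT_MAX_TOTAL = 30


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> PairwiseResult:
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and combined.size <= _EXACT_MAX_TOTAL:
        method = "exact"
    else:
        method = "asymptotic"  # tie-corrected normal approximation
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return PairwiseResult(
        u=float(res.statistic), p=float(min(res.pvalue, 1.0)),
        p_adjusted=None, method=method,
    )


def pairwise_mann_whitney(
    groups: Mapping[str, Sequence[float]], adjust: str = "none"
) -> dict[tuple[str, str], PairwiseResult]:
    """Two-sided Mann-Whitney U per group pair.

    Uses the exact null distribution when the pooled sample is small and
    tie-free, the tie-corrected normal approximation otherwise.  ``adjust``
    is one of ``none`` (default), ``bonferroni`` or ``holm``.
    """
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValidationError("need at least 2 groups")
    for name, a in arrays.items():
        if a.size == 0:
            raise ValidationError(f"group {name!r} is empty")
    pairs = list(itertools.combinations(arrays, 2))
    results = {pair: _mann_whitney(arrays[pair[0]], arrays[pair[1]]) for pair in pairs}
    if adjust != "none":
        raw = [results[p].p for p in pairs]
        adjusted = multipletests(raw, method=adjust)[1]
        for pair, padj in zip(pairs, adjusted):
            r = results[pair]
            results[pair] = PairwiseResult(
                u=r.u, p=r.p, p_adjusted=float(padj), method=r.method
            )
    return results


@dataclass
class GroupComparisonReport:
    """Comparison results for a set of parameters plus the normality log."""

    results: list[ComparisonResult]
    normality: pd.DataFrame
    alpha: float
    group_order: tuple[str, ...]
    adjust: str = "none"

    def to_frame(self) -> pd.DataFrame:
        """Long table: one row per (parameter, group), omnibus columns repeated."""
        rows = []
        for res in self.results:
            for group in self.group_order:
                if group not in res.summaries:
                    continue
                s = res.summaries[group]
                rows.append({
                    "parameter": res.parameter, "group": group, "n": s.n,
                    "mean": s.mean, "q1": s.q1, "q3": s.q3,
                    "ci_low": s.ci_low, "ci_high": s.ci_high,
                    "kruskal_wallis_H": res.kruskal_wallis_h,
                    "kruskal_wallis_p": res.kruskal_wallis_p,
                })
        return pd.DataFrame(rows)

    def posthoc_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.results:
            if res.pairwise is None:
                continue
            for (a, b), pr in res.pairwise.items():
                rows.append({
                    "parameter": res.parameter, "group_a": a, "group_b": b,
                    "U": pr.u, "p": pr.p, "p_adjusted": pr.p_adjusted,
                    "method": pr.method,
                })
        return pd.DataFrame(
            rows, columns=["parameter", "group_a", "group_b", "U", "p",
                           "p_adjusted", "method"],
        )


def compare_groups(
    table: pd.DataFrame,
    parameters: Sequence[str] = PARAMETERS,
    group_col: str = "group",
    group_order: Sequence[str] = DEFAULT_GROUP_ORDER,
    alpha: float = 0.05,
    adjust: str = "none",
) -> GroupComparisonReport:
    """Per-parameter group summaries, Kruskal-Wallis, gated post hoc tests.

    ``table`` is a per-recording kinematics table with a group column; only
    rows whose label appears in ``group_order`` enter the comparison.  Post
    hoc pairwise Mann-Whitney tests are run only when the omnibus p value is
    below ``alpha``.
    """
    if group_col not in table.columns:
        raise ValidationError(f"table lacks group column {group_col!r}")
    missing = [p for p in parameters if p not in table.columns]
    if missing:
        raise ValidationError(f"table lacks parameter columns {missing}")
    subset = table[table[group_col].isin(group_order)]
    present = [g for g in group_order if (subset[group_col] == g).any()]
    if len(present) < 2:
        raise ValidationError(
            f"need at least 2 non-empty groups among {tuple(group_order)}"
        )
    grouped = {g: subset.loc[subset[group_col] == g] for g in present}

    normality_rows = []
    results = []
    for param in parameters:
        values = {g: grouped[g][param].to_numpy(dtype=float) for g in present}
        for g, v in values.items():
            try:
                w, p = normality_test(v)
            except DegenerateDataError:
                w, p = np.nan, np.nan
            normality_rows.append({
                "parameter": param, "group": g, "shapiro_W": w, "shapiro_p": p,
                "nonnormal": bool(p < alpha) if np.isfinite(p) else True,
            })
        h, p_kw = kruskal_wallis(list(values.values()))
        pairwise = (
            pairwise_mann_whitney(values, adjust=adjust) if p_kw < alpha else None
        )
        summaries = {g: summarize_group(v) for g, v in values.items()}
        results.append(ComparisonResult(
            parameter=param, kruskal_wallis_h=h, kruskal_wallis_p=p_kw,
            summaries=summaries, pairwise=pairwise,
        ))
    return GroupComparisonReport(
        results=results,
        normality=pd.DataFrame(normality_rows),
        alpha=alpha,
        group_order=tuple(present),
        adjust=adjust,
    )
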