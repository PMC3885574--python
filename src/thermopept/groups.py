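"""Group-level thermogram statistics.

Mean/SD curves per clinical group, difference curves against the healthy
control group, box-chart percentile summaries of each shape metric, and
pairwise Mann-Whitney U tests between all group pairs for every metric.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import METRIC_NAMES
from .preprocess import ThermogramRecord
from .synthetic import THERMO_GROUPS

#: exact Mann-Whitney enumeration is used up to this many label assignments
EXACT_ENUMERATION_LIMIT = 20_000

#: percentile points of the box-chart summary
BOX_PERCENTILES = (1, 5, 25, 50, 75, 95, 99)


@dataclass(frozen=True)
class GroupSummary:
    """Pointwise mean and standard deviation curves of one group."""

    group: str
    temperatures: np.ndarray
    mean_curve: np.ndarray
    sd_curve: np.ndarray
    n: int


@dataclass(frozen=True)
class DifferenceCurve:
    """Group mean thermogram minus the control mean thermogram."""

    group: str
    temperatures: np.ndarray
    values: np.ndarray


@dataclass(frozen=True)
class BoxSummary:
    """Box-chart summary of one metric in one group."""

    metric: str
    group: str
    min: float
    p1: float
    p5: float
    p25: float
    p50: float
    p75: float
    p95: float
    p99: float
    max: float
    mean: float


@dataclass(frozen=True)
class PairwiseTestResult:
    """A two-sided Mann-Whitney comparison of one metric between groups."""

    metric: str
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    significance_band: str
    degenerate: bool = False


def _significance_band(p: float) -> str:
    if p < 0.05:
        return "p<0.05"
    if p < 0.1:
        return "0.05<=p<0.1"
    return "ns"


def group_thermograms(
    thermograms: dict[str, ThermogramRecord]
) -> dict[str, list[ThermogramRecord]]:
    """Bucket final thermograms by their group label."""
    grouped: dict[str, list[ThermogramRecord]] = {}
    for rec in thermograms.values():
        grouped.setdefault(rec.group, []).append(rec)
    return grouped


def group_mean_sd(
    grouped: dict[str, list[ThermogramRecord]]
) -> list[GroupSummary]:
    """Pointwise mean and (n-1)-denominator SD curves per group."""
    summaries = []
    for group, records in grouped.items():
        if not records:
            raise ValueError(f"group {group!r} is empty")
        grid = records[0].temperatures
        for rec in records:
            rec.require_stage("final")
            if not np.array_equal(rec.temperatures, grid):
                raise ValueError("all thermograms must share the common grid")
        values = np.array([rec.values for rec in records])
        mean = values.mean(axis=0)
        if len(records) == 1:
            warnings.warn(
                f"group {group!r} has a single sample; SD curve set to 0",
                stacklevel=2,
            )
            sd = np.zeros_like(mean)
        else:
            sd = values.std(axis=0, ddof=1)
        summaries.append(
            GroupSummary(
                group=group,
                temperatures=grid,
                mean_curve=mean,
                sd_curve=sd,
                n=len(records),
            )
        )
    return summaries


def difference_vs_control(
    summaries: list[GroupSummary], control_label: str = "control"
) -> list[DifferenceCurve]:
    """Each group's mean curve minus the control group's mean curve."""
    by_group = {s.group: s for s in summaries}
    if control_label not in by_group:
        raise ValueError(f"no group labelled {control_label!r}")
    control = by_group[control_label]
    return [
        DifferenceCurve(
            group=s.group,
            temperatures=s.temperatures,
            values=s.mean_curve - control.mean_curve,
        )
        for s in summaries
    ]


def box_summary(values, metric: str = "", group: str = "") -> BoxSummary:
    """Box-chart percentile summary (linear-interpolation convention)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty sample")
    pct = np.percentile(values, BOX_PERCENTILES)
    return BoxSummary(
        metric=metric,
        group=group,
        min=float(values.min()),
        p1=float(pct[0]),
        p5=float(pct[1]),
        p25=float(pct[2]),
        p50=float(pct[3]),
        p75=float(pct[4]),
        p95=float(pct[5]),
        p99=float(pct[6]),
        max=float(values.max()),
        mean=float(values.mean()),
    )


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(
    x,
    y,
    mode: str = "auto",
    metric: str = "",
    group_a: str = "",
    group_b: str = "",
) -> PairwiseTestResult:
    """Two-sided Mann-Whitney U test for unequal medians.

    ``U`` counts pairs with ``x_i > y_j`` plus half the ties.  ``auto``
    mode enumerates the exact permutation null when the number of label
    assignments C(n_x+n_y, n_x) is at most 20,000 and the pooled data are
    tie-free; otherwise it uses the normal approximation with tie and
    continuity corrections.  If every pooled value is identical the
    comparison is degenerate and p = 1.
    """
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return PairwiseTestResult(
            metric=metric,
            group_a=group_a,
            group_b=group_b,
            u_statistic=x.size * y.size / 2.0,
            p_value=1.0,
            significance_band="ns",
            degenerate=True,
        )

    if mode == "auto":
        n_assignments = math.comb(x.size + y.size, x.size)
        use_exact = n_assignments <= EXACT_ENUMERATION_LIMIT and not _has_ties(
            pooled
        )
        method = "exact" if use_exact else "asymptotic"
    else:
        method = "exact" if mode == "exact" else "asymptotic"

    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    p = float(min(res.pvalue, 1.0))
    return PairwiseTestResult(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        u_statistic=float(res.statistic),
        p_value=p,
        significance_band=_significance_band(p),
    )


def pairwise_metric_tests(
    metrics: pd.DataFrame,
    group_order: tuple[str, ...] = THERMO_GROUPS,
    metric_names: tuple[str, ...] = METRIC_NAMES,
    mode: str = "auto",
    bh_correct: bool = False,
) -> list[PairwiseTestResult]:
    """Mann-Whitney tests for every metric and unordered group pair.

    Pairs are emitted in the canonical order (control vs each disease
    group, then increasing disease pairs).  Raw p-values are reported by
    default; ``bh_correct`` applies Benjamini-Hochberg across all tests.
    """
    present = [g for g in group_order if g in set(metrics["group"])]
    skipped = [g for g in group_order if g not in present]
    if skipped:
        warnings.warn(f"groups with no samples skipped: {skipped}", stacklevel=2)
    if len(present) < 2:
        raise ValueError("need at least two non-empty groups")

    results = []
    for metric in metric_names:
        for ga, gb in itertools.combinations(present, 2):
            xa = metrics.loc[metrics["group"] == ga, metric].to_numpy()
            xb = metrics.loc[metrics["group"] == gb, metric].to_numpy()
            results.append(
                mann_whitney_u(
                    xa, xb, mode=mode, metric=metric, group_a=ga, group_b=gb
                )
            )
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(
            [r.p_value for r in results], method="fdr_bh"
        )
        results = [
            PairwiseTestResult(
                metric=r.metric,
                group_a=r.group_a,
                group_b=r.group_b,
                u_statistic=r.u_statistic,
                p_value=float(p),
                significance_band=_significance_band(float(p)),
                degenerate=r.degenerate,
            )
            for r, p in zip(results, adj)
        ]
    return results


def metric_summary_table(
    metrics: pd.DataFrame,
    group_order: tuple[str, ...] = THERMO_GROUPS,
    metric_names: tuple[str, ...] = METRIC_NAMES,
) -> pd.DataFrame:
    """Median (lower quartile, upper quartile) of each metric per group."""
    rows = []
    for metric in metric_names:
        for group in group_order:
            vals = metrics.loc[metrics["group"] == group, metric].to_numpy()
            if vals.size == 0:
                continue
            rows.append(
                {
                    "metric": metric,
                    "group": group,
                    "median": float(np.percentile(vals, 50)),
                    "lq": float(np.percentile(vals, 25)),
                    "uq": float(np.percentile(vals, 75)),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def pairwise_tests_table(results: list[PairwiseTestResult]) -> pd.DataFrame:
    """Pairwise test results as a tidy DataFrame."""
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "group_a": r.group_a,
                "group_b": r.group_b,
                "u_statistic": r.u_statistic,
                "p_value": r.p_value,
                "significance_band": r.significance_band,
            }
            for r in results
        ]
    )
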