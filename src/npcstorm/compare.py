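"""Two-group statistics and report assembly for pipeline outputs.

The primary comparison is the two-sample t test between conditions
(e.g. progenitor vs differentiated nuclei), pooled-variance Student by
default with Welch available for unequal variances. Summaries are reported
as mean ± s.d. A thin one-way ANOVA + Tukey HSD pass-through covers
three-or-more-group panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError, ParameterError, SchemaError


@dataclass
class GroupComparison:
    """One metric's two-group test: samples, t statistic, df, p, mean ± s.d."""

    metric: str
    group_a: np.ndarray
    group_b: np.ndarray
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    variant: str = "student"


def _check_sample(v, name: str) -> np.ndarray:
    arr = np.asarray(v, float)
    if arr.ndim != 1 or len(arr) < 2:
        raise ParameterError(f"sample {name} needs >= 2 values")
    if not np.isfinite(arr).all():
        raise ParameterError(f"sample {name} contains non-finite values")
    return arr


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "student",
    metric: str = "",
) -> GroupComparison:
    """Two-sided two-sample t test, pooled-variance (``student``) or ``welch``.

    Both samples identical in variance zero: equal means give the
    conventional t = 0, p = 1; unequal means are a degenerate-variance
    error (the statistic is infinite).
    """
    if variant not in ("student", "welch"):
        raise ParameterError(f"unknown t-test variant {variant!r}")
    a = _check_sample(a, "a")
    b = _check_sample(b, "b")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)

    if variant == "student":
        dof = na + nb - 2.0
        pooled = ((na - 1) * va + (nb - 1) * vb) / dof
        degenerate = pooled == 0.0
    else:
        num = (va / na + vb / nb) ** 2
        den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        dof = num / den if den > 0 else na + nb - 2.0
        degenerate = (va + vb) == 0.0

    if degenerate:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            raise DegenerateVarianceError(
                "zero within-group variance with unequal means"
            )
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=(variant == "student"))
        t_stat, p = float(t_stat), float(p)

    return GroupComparison(
        metric=metric,
        group_a=a,
        group_b=b,
        t_statistic=t_stat,
        degrees_of_freedom=float(dof),
        p_value=p,
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        variant=variant,
    )


def anova_oneway(groups: Mapping[str, Sequence[float]]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA across >= 3 groups with Tukey HSD post-hoc pairs.

    Returns (F, p, tukey table). Tukey HSD is computed with
    ``scipy.stats.tukey_hsd``.
    """
    names = list(groups)
    if len(names) < 3:
        raise ParameterError("anova_oneway expects >= 3 groups; use two_sample_t")
    samples = [_check_sample(groups[n], n) for n in names]
    f_stat, p = stats.f_oneway(*samples)
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append(
                dict(
                    group_a=names[i],
                    group_b=names[j],
                    mean_diff=float(np.mean(samples[i]) - np.mean(samples[j])),
                    p_adj=float(res.pvalue[i, j]),
                )
            )
    return float(f_stat), float(p), pd.DataFrame(rows)


DEFAULT_METRICS = (
    "npc_density",
    "sml_density",
    "mean_sml_per_cluster",
    "mean_diameter_nm",
)


def build_report(
    stats_table: pd.DataFrame,
    metrics: Sequence[str] = DEFAULT_METRICS,
    group_col: str = "group",
    variant: str = "student",
    out_dir: str | Path | None = None,
    make_figures: bool = False,
) -> pd.DataFrame:
    """Per-metric two-group comparison table from a tidy per-nucleus table.

    The table must carry ``group_col`` with exactly two levels; each metric
    column yields one row: group means ± s.d., t, df and the two-sided p.
    Missing metric columns raise :class:`SchemaError`. Deterministic given
    inputs; optional scatter figures are written under ``out_dir``.
    """
    if group_col not in stats_table.columns:
        raise SchemaError(f"missing group column {group_col!r}")
    report_cols = [
        "metric", "group_a", "group_b", "n_a", "n_b",
        "mean_a", "sd_a", "mean_b", "sd_b",
        "t_statistic", "degrees_of_freedom", "p_value",
    ]
    if len(metrics) == 0:
        report = pd.DataFrame(columns=report_cols)
    else:
        levels = sorted(stats_table[group_col].unique())
        if len(levels) != 2:
            raise SchemaError(f"expected 2 groups, found {levels}")
        ga, gb = levels
        rows = []
        for metric in metrics:
            if metric not in stats_table.columns:
                raise SchemaError(f"missing metric column {metric!r}")
            a = stats_table.loc[stats_table[group_col] == ga, metric].dropna()
            b = stats_table.loc[stats_table[group_col] == gb, metric].dropna()
            cmp = two_sample_t(a, b, variant=variant, metric=metric)
            rows.append(
                dict(
                    metric=metric,
                    group_a=ga,
                    group_b=gb,
                    n_a=len(a),
                    n_b=len(b),
                    mean_a=cmp.mean_a,
                    sd_a=cmp.sd_a,
                    mean_b=cmp.mean_b,
                    sd_b=cmp.sd_b,
                    t_statistic=cmp.t_statistic,
                    degrees_of_freedom=cmp.degrees_of_freedom,
                    p_value=cmp.p_value,
                )
            )
        report = pd.DataFrame(rows, columns=report_cols)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "comparisons.csv", index=False)
        if make_figures and len(report):
            _scatter_figures(stats_table, metrics, group_col, out)
    return report


def _scatter_figures(
    stats_table: pd.DataFrame, metrics: Sequence[str], group_col: str, out: Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    levels = sorted(stats_table[group_col].unique())
    for metric in metrics:
        fig, ax = plt.subplots(figsize=(3, 3))
        for i, g in enumerate(levels):
            vals = stats_table.loc[stats_table[group_col] == g, metric].dropna()
            x = np.full(len(vals), i, float)
            ax.scatter(x + np.linspace(-0.1, 0.1, len(vals)), vals, s=12)
            ax.errorbar(
                i, vals.mean(), yerr=vals.std(ddof=1),
                fmt="_", color="k", capsize=4,
            )
        ax.set_xticks(range(len(levels)), levels)
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(out / f"{metric}.png", dpi=120)
        plt.close(fig)
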