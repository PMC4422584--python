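"""Statistics layer: pooled t-tests, per-day normalization, tail probabilities, reports.

Group comparisons use the classical two-sample Student's t-test with pooled
variance (not Welch). Calcium responses of a knockdown condition are
normalized per experiment day by the same-day control mean; the across-day
mean ± SD then feeds a one-sided normal tail probability above 100 % — the
chance that a normal variable with the experimental mean and SD exceeds the
control level.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import norm
from scipy.stats import t as t_dist

__all__ = [
    "ConditionSummary",
    "NormalizedResponse",
    "student_t_two_tailed",
    "normalize_by_day",
    "normal_tail_above",
    "build_report",
]

logger = logging.getLogger(__name__)


def student_t_two_tailed(sample_a, sample_b) -> float:
    """Two-tailed p-value of the pooled-variance two-sample t-test.

    Degenerate contract when the pooled variance is zero: p = 1 for equal
    means, p = 0 for unequal means.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        return 1.0 if diff == 0.0 else 0.0
    tstat = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return float(2.0 * t_dist.sf(abs(tstat), df))


@dataclass
class ConditionSummary:
    """Per-condition replicate values with mean and standard error."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size == 0:
            raise ValueError(f"condition {self.label!r} has no values")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def sem(self) -> float:
        """SD / sqrt(n); NaN for a single replicate."""
        if self.n < 2:
            return float("nan")
        return float(self.values.std(ddof=1) / np.sqrt(self.n))


@dataclass
class NormalizedResponse:
    """Day-normalized treatment response in percent of same-day control.

    ``normalized_pct[d] = 100 * mean(treatment_d) / mean(control_d)``;
    ``mean_pct`` and ``sd_pct`` summarize across days (``sd_pct`` is the
    sample SD over day-level values, None for a single day).
    """

    days: list
    treatment_means: np.ndarray
    control_means: np.ndarray
    normalized_pct: np.ndarray

    @property
    def mean_pct(self) -> float:
        return float(self.normalized_pct.mean())

    @property
    def sd_pct(self) -> float | None:
        if self.normalized_pct.size < 2:
            return None
        return float(self.normalized_pct.std(ddof=1))


def normalize_by_day(treatment_by_day: dict, control_by_day: dict) -> NormalizedResponse:
    """Normalize per-day treatment means by same-day control means.

    Both mappings are ``{day: values}`` and must cover the same days; a day
    whose control mean is <= 0 is an error.
    """
    days = sorted(treatment_by_day)
    if not days:
        raise ValueError("need at least one day")
    if sorted(control_by_day) != days:
        raise ValueError("treatment and control must cover the same days")
    t_means, c_means, pct = [], [], []
    for day in days:
        tm = float(np.mean(treatment_by_day[day]))
        cm = float(np.mean(control_by_day[day]))
        if cm <= 0:
            raise ValueError(f"control mean <= 0 on day {day!r}")
        t_means.append(tm)
        c_means.append(cm)
        pct.append(100.0 * tm / cm)
    return NormalizedResponse(
        days, np.array(t_means), np.array(c_means), np.array(pct)
    )


def normal_tail_above(mean_pct: float, sd_pct: float, threshold_pct: float = 100.0) -> float:
    """P(X > threshold) for X ~ Normal(mean, sd), i.e. 1 - Phi((thr - mean)/sd)."""
    if not sd_pct > 0:
        raise ValueError("sd must be > 0")
    return float(norm.sf((threshold_pct - mean_pct) / sd_pct))


def build_report(
    summaries: list[ConditionSummary],
    out_dir: str | Path,
    title: str = "Condition comparison",
) -> dict[str, Path]:
    """Write summary table, pairwise p-value matrix, and a bar chart.

    Outputs ``summary.csv`` (condition, n, mean, sem), ``pvalues.csv``
    (pooled-t p-value for every condition pair) and ``barplot.png`` (bars
    with SEM error bars, in input order). Deterministic for fixed inputs.
    """
    if not summaries:
        raise ValueError("no condition summaries to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("writing report for %d conditions to %s", len(summaries), out)

    summary_path = out / "summary.csv"
    with open(summary_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["condition", "n", "mean", "sem"])
        for s in summaries:
            writer.writerow([s.label, s.n, repr(s.mean), repr(s.sem)])

    pvalues_path = out / "pvalues.csv"
    labels = [s.label for s in summaries]
    with open(pvalues_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["condition"] + labels)
        for sa in summaries:
            row = [sa.label]
            for sb in summaries:
                if sa is sb:
                    row.append("")
                elif sa.n < 2 or sb.n < 2:
                    row.append("nan")
                else:
                    row.append(repr(student_t_two_tailed(sa.values, sb.values)))
            writer.writerow(row)

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(summaries), 4))
    means = [s.mean for s in summaries]
    sems = [0.0 if np.isnan(s.sem) else s.sem for s in summaries]
    ax.bar(labels, means, yerr=sems, capsize=4, color="#6699cc", edgecolor="k")
    ax.set_ylabel("mean ± SEM")
    ax.set_title(title)
    fig.tight_layout()
    plot_path = out / "barplot.png"
    fig.savefig(plot_path, dpi=120)
    plt.close(fig)

    return {"summary": summary_path, "pvalues": pvalues_path, "barplot": plot_path}
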