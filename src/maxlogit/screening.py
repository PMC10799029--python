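"""Candidate-gene screening (MVS-CGS).

"Merging variable selections and common ground seeking": per-gene class
statistics (mean, SD, and Sharpe ratio mean/SD within tumors and controls)
are turned into absolute relative changes; percentile tails of each ranking
propose genes; a class-separation filter (what fraction of tumors lies
beyond the most extreme control value) prunes each proposal; the survivors
are unioned.  Optionally the whole procedure is repeated on squared
expression values and the two candidate sets intersected.

Because every statistic is a ratio of within-cohort quantities, the screen
is invariant to rescaling a cohort, which is what lets it run on RNA-seq,
microarray and RT-PCR data without harmonisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .core import CohortDataset

METRICS = ("mean", "sd", "sharpe")


@dataclass(frozen=True)
class ScreeningConfig:
    """Percentile tails, separation thresholds, and the squared-pass flag.

    Defaults follow the published procedure: bottom 1% of mean changes,
    top 15% of SD changes, top 5% of Sharpe-ratio changes; separation
    thresholds 0.5 (Sharpe set), 0.7 (mean set), 0.8 (SD set).
    ``mean_tail`` exists because a *bottom* tail on mean changes is a
    surprising (though literal) rule; set it to "top" for the conventional
    reading.
    """

    pct_mean: float = 1.0
    pct_sd: float = 15.0
    pct_sharpe: float = 5.0
    mean_tail: str = "bottom"
    sep_threshold_sharpe: float = 0.5
    sep_threshold_mean: float = 0.7
    sep_threshold_sd: float = 0.8
    use_squared_transform: bool = False

    def __post_init__(self) -> None:
        for p in (self.pct_mean, self.pct_sd, self.pct_sharpe):
            if not (0.0 < p <= 100.0):
                raise ValueError("percentile tails must lie in (0, 100]")
        for t in (self.sep_threshold_sharpe, self.sep_threshold_mean, self.sep_threshold_sd):
            if not (0.0 <= t <= 1.0):
                raise ValueError("separation thresholds must lie in [0, 1]")
        if self.mean_tail not in ("bottom", "top"):
            raise ValueError("mean_tail must be 'bottom' or 'top'")

    def tail_for(self, metric: str) -> str:
        return self.mean_tail if metric == "mean" else "top"

    def pct_for(self, metric: str) -> float:
        return {"mean": self.pct_mean, "sd": self.pct_sd, "sharpe": self.pct_sharpe}[metric]

    def sep_threshold_for(self, metric: str) -> float:
        return {
            "mean": self.sep_threshold_mean,
            "sd": self.sep_threshold_sd,
            "sharpe": self.sep_threshold_sharpe,
        }[metric]


def class_stats(cohort: CohortDataset, squared: bool = False) -> pd.DataFrame:
    """Per-gene class statistics and absolute relative changes.

    Relative change of a quantity q is |q_T - q_N| / |q_N| (controls as
    base class).  A change is NaN-flagged when its base is zero; a Sharpe
    ratio is NaN-flagged when the class SD is zero.  Flagged genes are
    excluded from the affected ranking only.
    """
    tumors = cohort.labels == 1
    controls = cohort.labels == 0
    if tumors.sum() < 2 or controls.sum() < 2:
        raise ValueError(
            f"cohort {cohort.cohort_id!r} needs at least two samples per class"
        )
    X = cohort.expression**2 if squared else cohort.expression
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_t = X[tumors].mean(axis=0)
        mean_n = X[controls].mean(axis=0)
        sd_t = X[tumors].std(axis=0, ddof=1)
        sd_n = X[controls].std(axis=0, ddof=1)
        sharpe_t = np.where(sd_t > 0, mean_t / np.where(sd_t > 0, sd_t, 1.0), np.nan)
        sharpe_n = np.where(sd_n > 0, mean_n / np.where(sd_n > 0, sd_n, 1.0), np.nan)

    def rel_change(q_t, q_n):
        base = np.abs(q_n)
        return np.where(base > 0, np.abs(q_t - q_n) / np.where(base > 0, base, 1.0), np.nan)

    stats = pd.DataFrame(
        {
            "mean_T": mean_t,
            "mean_N": mean_n,
            "sd_T": sd_t,
            "sd_N": sd_n,
            "sharpe_T": sharpe_t,
            "sharpe_N": sharpe_n,
            "rc_mean": rel_change(mean_t, mean_n),
            "rc_sd": rel_change(sd_t, sd_n),
            "rc_sharpe": rel_change(sharpe_t, sharpe_n),
        },
        index=pd.Index(cohort.gene_ids, name="gene"),
    )
    return stats


def percentile_screen(stats: pd.DataFrame, config: ScreeningConfig) -> Dict[str, Set[str]]:
    """Per-metric percentile tails over the sorted absolute relative changes.

    Selection size is ceil(tail fraction x eligible genes); ties are broken
    by stable gene-identifier order.
    """
    kept: Dict[str, Set[str]] = {}
    for metric in METRICS:
        col = stats[f"rc_{metric}"]
        eligible = col.dropna()
        if eligible.empty:
            kept[metric] = set()
            continue
        n_keep = math.ceil(config.pct_for(metric) / 100.0 * len(eligible))
        frame = eligible.rename("rc").reset_index()
        ascending = config.tail_for(metric) == "bottom"
        frame = frame.sort_values(["rc", "gene"], ascending=[ascending, True], kind="stable")
        kept[metric] = set(frame["gene"].iloc[:n_keep])
    return kept


def separation_filter(
    cohort: CohortDataset,
    genes: Sequence[str],
    threshold: float,
    squared: bool = False,
) -> Set[str]:
    """Keep genes whose tumor values clear the control extremes often enough.

    If the tumor class mean exceeds the control mean, the gene survives when
    the proportion of tumor samples above the control *maximum* is >= the
    threshold (inclusive); symmetrically below the control minimum when the
    tumor mean is lower.  Equal class means have no direction and drop.
    """
    genes = [g for g in genes]
    if not genes:
        return set()
    X = cohort.gene_columns(genes)
    if squared:
        X = X**2
    tumors = cohort.labels == 1
    controls = cohort.labels == 0
    kept: Set[str] = set()
    for i, gene in enumerate(genes):
        vt, vn = X[tumors, i], X[controls, i]
        tm, nm = vt.mean(), vn.mean()
        if tm > nm:
            prop = float(np.mean(vt > vn.max()))
        elif tm < nm:
            prop = float(np.mean(vt < vn.min()))
        else:
            continue
        if prop >= threshold:
            kept.add(gene)
    return kept


def _single_pass(cohort: CohortDataset, config: ScreeningConfig, squared: bool) -> Set[str]:
    stats = class_stats(cohort, squared=squared)
    kept = percentile_screen(stats, config)
    survivors: Set[str] = set()
    for metric in METRICS:
        survivors |= separation_filter(
            cohort,
            sorted(kept[metric]),
            config.sep_threshold_for(metric),
            squared=squared,
        )
    return survivors


def mvs_cgs(cohort: CohortDataset, config: Optional[ScreeningConfig] = None) -> Set[str]:
    """Run the full screen on a cohort; returns the candidate gene set."""
    config = config or ScreeningConfig()
    candidates = _single_pass(cohort, config, squared=False)
    if config.use_squared_transform:
        candidates &= _single_pass(cohort, config, squared=True)
    return candidates


def screen_cohorts(cohorts: Sequence[CohortDataset], config: Optional[ScreeningConfig] = None) -> Set[str]:
    """Union of per-cohort candidate sets, restricted to the shared universe.

    Merging per-cohort selections keeps genes whose signal is strong in any
    one platform; the downstream multi-cohort search is what enforces common
    ground across all of them.
    """
    config = config or ScreeningConfig()
    shared = set(cohorts[0].gene_ids)
    for c in cohorts[1:]:
        shared &= set(c.gene_ids)
    merged: Set[str] = set()
    for c in cohorts:
        merged |= mvs_cgs(c, config)
    return merged & shared


def screening_report(cohort: CohortDataset, config: Optional[ScreeningConfig] = None) -> pd.DataFrame:
    """Per-gene table of statistics, per-filter kept/dropped flags, and the
    stage that removed each gene."""
    config = config or ScreeningConfig()
    stats = class_stats(cohort)
    kept = percentile_screen(stats, config)
    report = stats.copy()
    final: Set[str] = set()
    for metric in METRICS:
        in_tail = stats.index.isin(list(kept[metric]))
        survived = separation_filter(
            cohort, sorted(kept[metric]), config.sep_threshold_for(metric)
        )
        report[f"kept_pct_{metric}"] = in_tail
        report[f"kept_sep_{metric}"] = stats.index.isin(sorted(survived))
        final |= survived
    report["candidate"] = report.index.isin(sorted(final))

    def removed_by(row):
        if row["candidate"]:
            return ""
        if not any(row[f"kept_pct_{m}"] for m in METRICS):
            return "percentile"
        return "separation"

    report["removed_by"] = report.apply(removed_by, axis=1)
    return report
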