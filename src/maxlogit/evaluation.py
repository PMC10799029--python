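"""Metrics, classifier-defined patient subgroups, and stratified evaluation."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, List, Optional, Sequence

import numpy as np
import pandas as pd

from .core import CohortDataset, MaxLogisticClassifier, risk_probability
from .search import SearchConfig, fit_coefficients


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding (half away from zero), e.g. 90.965 -> 90.97."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMetrics:
    """Confusion counts with percent metrics; undefined metrics stay None."""

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def accuracy(self) -> Optional[float]:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else None

    @property
    def sensitivity(self) -> Optional[float]:
        pos = self.tp + self.fn
        return 100.0 * self.tp / pos if pos else None

    @property
    def specificity(self) -> Optional[float]:
        neg = self.tn + self.fp
        return 100.0 * self.tn / neg if neg else None

    def display(self) -> dict:
        fmt = lambda v: None if v is None else round_half_up(v, 2)
        return {
            "accuracy": fmt(self.accuracy),
            "sensitivity": fmt(self.sensitivity),
            "specificity": fmt(self.specificity),
        }

    def __add__(self, other: "ConfusionMetrics") -> "ConfusionMetrics":
        return ConfusionMetrics(
            self.tp + other.tp, self.fn + other.fn, self.tn + other.tn, self.fp + other.fp
        )


def confusion_metrics(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionMetrics:
    pred = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    return ConfusionMetrics(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
    )


def evaluate_cohort(classifier: MaxLogisticClassifier, cohort: CohortDataset) -> ConfusionMetrics:
    return confusion_metrics(classifier.predict(cohort), cohort.labels)


# ---------------------------------------------------------------------------
# subgroups ("Venn" assignment)
# ---------------------------------------------------------------------------


def subgroup_assignment(factor_scores: Sequence[float]) -> FrozenSet[int]:
    """Indices of factors whose score exceeds 0 (per-factor p > 0.5).

    An empty set means no factor detects the sample (predicted control).
    """
    scores = np.asarray(factor_scores, dtype=float)
    if scores.size < 1:
        raise ValueError("at least one factor score is required")
    return frozenset(int(j) for j in np.flatnonzero(scores > 0))


def subgroup_counts(
    classifier: MaxLogisticClassifier, cohort: CohortDataset
) -> Dict[FrozenSet[int], int]:
    """Tumor-sample counts per detecting-factor combination.

    Counts cover tumor samples only; the non-empty combinations sum to the
    number of correctly detected tumors (max > 0 iff some factor > 0).
    """
    scores = classifier.factor_scores(cohort)
    counts: Dict[FrozenSet[int], int] = {}
    for i in np.flatnonzero(cohort.labels == 1):
        key = subgroup_assignment(scores[i])
        counts[key] = counts.get(key, 0) + 1
    return counts


def subgroup_table(classifier: MaxLogisticClassifier, cohort: CohortDataset) -> pd.DataFrame:
    """Readable subgroup table: one row per factor combination."""
    counts = subgroup_counts(classifier, cohort)
    rows = []
    for key in sorted(counts, key=lambda k: (len(k), sorted(k))):
        name = "none" if not key else "&".join(f"CF{j + 1}" for j in sorted(key))
        rows.append({"subgroup": name, "tumors": counts[key]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratified and pooled evaluation
# ---------------------------------------------------------------------------


def stratified_evaluate(
    cohort: CohortDataset,
    classifier: MaxLogisticClassifier,
    refit: bool = False,
    config: Optional[SearchConfig] = None,
) -> Dict[str, ConfusionMetrics]:
    """Per-stratum metrics.

    ``refit=False`` applies the given classifier within each stratum
    (direct check); ``refit=True`` refits the coefficients on the same gene
    partition within each stratum and keeps the refit only when it lowers
    the stratum's 0-1 count, so a refit never scores below the direct
    check on its own training stratum.  Strata with a single class are
    reported with whatever metrics remain defined.
    """
    if cohort.strata is None:
        raise ValueError(f"cohort {cohort.cohort_id!r} carries no strata")
    out: Dict[str, ConfusionMetrics] = {}
    for stratum in sorted(set(cohort.strata)):
        rows = np.flatnonzero(cohort.strata == stratum)
        sub = cohort.subset(rows)
        direct = evaluate_cohort(classifier, sub)
        if refit and sub.labels.min() != sub.labels.max():
            local = fit_coefficients(classifier.partition, [sub], config)
            refitted = evaluate_cohort(local, sub)
            if refitted.tp + refitted.tn > direct.tp + direct.tn:
                direct = refitted
        out[str(stratum)] = direct
    return out


def pooled_metrics(reports: Sequence[ConfusionMetrics]) -> ConfusionMetrics:
    """Sum confusion counts across cohorts and recompute percent metrics."""
    if not reports:
        raise ValueError("at least one report is required")
    total = ConfusionMetrics(0, 0, 0, 0)
    for r in reports:
        total = total + r
    return total


def metrics_table(per_cohort: Dict[str, ConfusionMetrics]) -> pd.DataFrame:
    """Cohort-per-row table with percent metrics and a pooled bottom row."""
    rows = []
    for cid, m in per_cohort.items():
        rows.append({"cohort": cid, "n": m.n, **m.display(),
                     "tp": m.tp, "fn": m.fn, "tn": m.tn, "fp": m.fp})
    pooled = pooled_metrics(list(per_cohort.values()))
    rows.append({"cohort": "pooled", "n": pooled.n, **pooled.display(),
                 "tp": pooled.tp, "fn": pooled.fn, "tn": pooled.tn, "fp": pooled.fp})
    return pd.DataFrame(rows)


def risk_table(classifier: MaxLogisticClassifier, cohort: CohortDataset) -> pd.DataFrame:
    """Per-sample risk output: label, winning score, probability, subgroup."""
    scores = classifier.factor_scores(cohort)
    logodds = scores.max(axis=1)
    probs = risk_probability(logodds)
    rows = []
    for i, sid in enumerate(cohort.sample_ids):
        key = subgroup_assignment(scores[i])
        rows.append(
            {
                "sample": sid,
                "label": int(cohort.labels[i]),
                "cf_max": logodds[i],
                "p_max": probs[i],
                "predicted": int(probs[i] > classifier.threshold),
                "subgroup": "" if not key else "&".join(f"CF{j + 1}" for j in sorted(key)),
            }
        )
    return pd.DataFrame(rows)
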