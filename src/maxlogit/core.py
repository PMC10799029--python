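"""Max-logistic competing risk factor model.

A sample's log-odds of disease is the *maximum* of several linear predictors
("competing factors"), each built on its own small gene group:

    log(p / (1 - p)) = max_j ( b_0j + x[S_j] . b_j ),   j = 1..G

With a single active factor this reduces to classical logistic regression.
Model selection minimises the 0-1 misclassification count at the 0.5
probability threshold, summed over K heterogeneous cohorts, plus a sparsity
penalty on the size of the gene union and the number of factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

#: Intercept value marking a factor as inactive.  An inactive factor loses
#: every max comparison and is never fed to the exponential.
INACTIVE = float("-inf")


class GeneLookupError(KeyError):
    """Raised when a classifier references genes absent from a cohort."""

    def __init__(self, missing: Sequence[str], cohort_id: str = ""):
        self.missing = tuple(missing)
        self.cohort_id = cohort_id
        where = f" in cohort {cohort_id!r}" if cohort_id else ""
        super().__init__(f"genes not found{where}: {', '.join(self.missing)}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CohortDataset:
    """One cohort: expression matrix (samples x genes), binary labels, strata.

    Labels are 1 for tumor, 0 for control.  Expression stays on the cohort's
    native measurement scale; cross-cohort harmonisation is deliberately not
    performed (the model is fit per cohort).
    """

    cohort_id: str
    expression: np.ndarray
    labels: np.ndarray
    gene_ids: Sequence[str]
    strata: Optional[np.ndarray] = None
    sample_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.gene_ids = list(self.gene_ids)
        if self.expression.ndim != 2:
            raise ValueError("expression must be a 2-D samples x genes matrix")
        n, g = self.expression.shape
        if len(self.labels) != n:
            raise ValueError(
                f"{len(self.labels)} labels for {n} expression rows in "
                f"cohort {self.cohort_id!r}"
            )
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length must match expression columns")
        if len(set(self.gene_ids)) != g:
            raise ValueError(f"duplicate gene identifiers in cohort {self.cohort_id!r}")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 (control) or 1 (tumor)")
        if not np.isfinite(self.expression).all():
            raise ValueError(f"non-finite expression values in cohort {self.cohort_id!r}")
        if self.strata is not None:
            self.strata = np.asarray(self.strata, dtype=object)
            if len(self.strata) != n:
                raise ValueError("strata length must match sample count")
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1:04d}" for i in range(n)]
        else:
            self.sample_ids = list(self.sample_ids)
            if len(self.sample_ids) != n:
                raise ValueError("sample_ids length must match sample count")
        self._index = {g_: i for i, g_ in enumerate(self.gene_ids)}

    @property
    def n_samples(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def gene_columns(self, genes: Sequence[str]) -> np.ndarray:
        """Submatrix for the requested genes, in the requested order."""
        missing = [g for g in genes if g not in self._index]
        if missing:
            raise GeneLookupError(missing, self.cohort_id)
        idx = [self._index[g] for g in genes]
        return self.expression[:, idx]

    def subset(self, rows: np.ndarray, cohort_id: Optional[str] = None) -> "CohortDataset":
        return CohortDataset(
            cohort_id=cohort_id or self.cohort_id,
            expression=self.expression[rows],
            labels=self.labels[rows],
            gene_ids=self.gene_ids,
            strata=None if self.strata is None else self.strata[rows],
            sample_ids=[self.sample_ids[i] for i in np.flatnonzero(np.asarray(rows))]
            if np.asarray(rows).dtype == bool
            else [self.sample_ids[i] for i in rows],
        )


@dataclass(frozen=True)
class CompetingFactor:
    """One linear risk factor: intercept + coefficients over an ordered gene group.

    ``intercept == INACTIVE`` marks the factor as switched off (it scores
    below every finite competitor, recovering classical logistic regression
    when only one factor remains active).
    """

    intercept: float
    coefficients: tuple
    genes: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.coefficients) != len(self.genes):
            raise ValueError("coefficient vector length must equal gene group size")
        if self.intercept != INACTIVE and not math.isfinite(self.intercept):
            raise ValueError("intercept must be finite or the inactive sentinel")
        if not all(math.isfinite(c) for c in self.coefficients):
            raise ValueError("coefficients must be finite")

    @property
    def active(self) -> bool:
        return self.intercept != INACTIVE

    @classmethod
    def inactive(cls, genes: Sequence[str]) -> "CompetingFactor":
        return cls(INACTIVE, (0.0,) * len(genes), tuple(genes))


@dataclass(frozen=True)
class GenePartition:
    """Ordered gene groups S_1..S_G over a shared gene universe.

    Groups may overlap (a gene can serve in several competing factors); the
    union S_u is what the sparsity penalty of the selection objective sees.
    """

    groups: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(tuple(g) for g in self.groups))
        if len(self.groups) < 1:
            raise ValueError("a partition needs at least one group")
        for g in self.groups:
            if len(set(g)) != len(g):
                raise ValueError(f"duplicate gene within group {g}")

    @property
    def G(self) -> int:
        return len(self.groups)

    @property
    def sizes(self) -> tuple:
        return tuple(len(g) for g in self.groups)

    @property
    def union(self) -> frozenset:
        return frozenset(g for grp in self.groups for g in grp)

    def canonical(self) -> tuple:
        """Order-insensitive key (used for tie-breaking / deduplication)."""
        return tuple(sorted(tuple(sorted(g)) for g in self.groups))


@dataclass(frozen=True)
class PenaltyConfig:
    """Tuning weights of the selection objective; both must be non-negative."""

    lambda1: float = 0.0
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("lambda1 and lambda2 must be non-negative")


@dataclass
class MaxLogisticClassifier:
    """A shared partition with per-cohort competing factors.

    ``per_cohort_factors`` maps cohort id to a list of G factors, aligned to
    ``partition.groups``.  Coefficients are cohort-specific (the model is fit
    independently per cohort); only the gene groups are shared.
    """

    partition: GenePartition
    per_cohort_factors: dict = field(default_factory=dict)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly inside (0, 1)")
        for cid, factors in self.per_cohort_factors.items():
            if len(factors) != self.partition.G:
                raise ValueError(f"cohort {cid!r} must carry {self.partition.G} factors")
            for f, grp in zip(factors, self.partition.groups):
                if len(f.coefficients) != len(grp):
                    raise ValueError(
                        f"factor of cohort {cid!r} has {len(f.coefficients)} "
                        f"coefficients for group of size {len(grp)}"
                    )

    def factors_for(self, cohort_id: str):
        try:
            return self.per_cohort_factors[cohort_id]
        except KeyError:
            raise KeyError(f"no factors fitted for cohort {cohort_id!r}") from None

    def factor_scores(self, cohort: CohortDataset) -> np.ndarray:
        """(n_samples, G) matrix of linear factor scores on a cohort."""
        factors = self.factors_for(cohort.cohort_id)
        out = np.empty((cohort.n_samples, self.partition.G))
        for j, (factor, genes) in enumerate(zip(factors, self.partition.groups)):
            if not factor.active:
                out[:, j] = INACTIVE
            else:
                X = cohort.gene_columns(genes)
                out[:, j] = factor.intercept + X @ np.asarray(factor.coefficients)
        return out

    def max_logodds(self, cohort: CohortDataset) -> np.ndarray:
        scores = self.factor_scores(cohort)
        if not any(f.active for f in self.factors_for(cohort.cohort_id)):
            raise ValueError("all competing factors are inactive")
        return scores.max(axis=1)

    def predict_proba(self, cohort: CohortDataset) -> np.ndarray:
        return risk_probability(self.max_logodds(cohort))

    def predict(self, cohort: CohortDataset) -> np.ndarray:
        p = self.predict_proba(cohort)
        return (p > self.threshold).astype(int)


# ---------------------------------------------------------------------------
# scoring operations
# ---------------------------------------------------------------------------


def linear_factor_score(expr_row: Sequence[float], factor: CompetingFactor) -> float:
    """Score of one competing factor on one sample: intercept + x . beta.

    An inactive factor returns the sentinel that loses every max comparison.
    """
    if not factor.active:
        return INACTIVE
    x = np.asarray(expr_row, dtype=float)
    if x.shape != (len(factor.coefficients),):
        raise ValueError(
            f"expression row of length {x.size} does not match "
            f"{len(factor.coefficients)} coefficients"
        )
    if not np.isfinite(x).all():
        raise ValueError("non-finite expression values")
    return float(factor.intercept + x @ np.asarray(factor.coefficients))


def max_logodds(
    expr_row: Sequence[float],
    classifier: MaxLogisticClassifier,
    cohort_id: str,
    gene_ids: Sequence[str],
):
    """Max of the factor scores for one full expression row.

    Returns ``(logodds, winners)`` where winners is the tuple of factor
    indices attaining the maximum.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    x = np.asarray(expr_row, dtype=float)
    factors = classifier.factors_for(cohort_id)
    if not any(f.active for f in factors):
        raise ValueError("all competing factors are inactive")
    scores = []
    for factor, genes in zip(factors, classifier.partition.groups):
        missing = [g for g in genes if g not in index]
        if missing:
            raise GeneLookupError(missing, cohort_id)
        row = x[[index[g] for g in genes]]
        scores.append(linear_factor_score(row, factor))
    best = max(scores)
    winners = tuple(j for j, s in enumerate(scores) if s == best)
    return best, winners


def risk_probability(logodds):
    """Numerically stable logistic transform; the inactive sentinel maps to 0."""
    arr = np.asarray(logodds, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("log-odds must be finite or the inactive sentinel")
    out = expit(arr)
    if out.ndim == 0:
        return float(out)
    return out


def classify(prob: float, threshold: float = 0.5) -> int:
    """1 (tumor) iff prob > threshold; a tie at the threshold counts as control.

    The tie convention is forced by the error-counting objective, which charges
    an error for a tumor sample whenever p <= 0.5.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    return int(prob > threshold)


def misclassification_count(classifier: MaxLogisticClassifier, cohort: CohortDataset) -> int:
    """0-1 loss on a cohort: tumors with p <= t plus controls with p > t."""
    p = classifier.predict_proba(cohort)
    y = cohort.labels
    t = classifier.threshold
    return int(np.sum((p <= t) & (y == 1)) + np.sum((p > t) & (y == 0)))


# ---------------------------------------------------------------------------
# selection objective
# ---------------------------------------------------------------------------


def sparsity_penalty(su_size: int, G: int) -> float:
    """|S_u| - (|S_u| + G - 1) / ((|S_u| + 1) * G - 1).

    The subtracted fraction is monotone decreasing in both arguments, so the
    penalty favours few genes first and, among equal-size unions, fewer
    factors.
    """
    if su_size < 1 or G < 1:
        raise ValueError("su_size and G must be positive")
    denom = (su_size + 1) * G - 1
    if denom == 0:
        raise ValueError("degenerate penalty arguments")
    return su_size - (su_size + G - 1) / denom


def total_misclassifications(classifier: MaxLogisticClassifier, cohorts) -> int:
    return sum(misclassification_count(classifier, c) for c in cohorts)


def penalized_objective(
    classifier: MaxLogisticClassifier,
    cohorts: Sequence[CohortDataset],
    penalty: PenaltyConfig = PenaltyConfig(),
    form: str = "log",
) -> float:
    """Penalised selection objective over K cohorts.

    literal form:  (1 + l1 + |S_u|)**E  +  l2 * pen(|S_u|, G)
    log form:      log of the same quantity, computed as
                   logaddexp(E * log(1 + l1 + |S_u|), log(l2 * pen))

    E is the total 0-1 loss.  The log form never overflows and induces the
    same ordering as the literal formula wherever the latter is representable
    (log is strictly increasing).
    """
    E = total_misclassifications(classifier, cohorts)
    su = len(classifier.partition.union)
    G = classifier.partition.G
    base = 1.0 + penalty.lambda1 + su
    pen = penalty.lambda2 * sparsity_penalty(su, G)
    if form == "literal":
        return base**E + pen
    if form != "log":
        raise ValueError("form must be 'log' or 'literal'")
    log_first = E * math.log(base)
    if pen <= 0.0:
        return log_first
    return float(np.logaddexp(log_first, math.log(pen)))
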