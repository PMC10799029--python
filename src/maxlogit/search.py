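"""Monte-Carlo subset search and coefficient fitting across cohorts.

The exact selection problem - minimise the penalised 0-1 objective over all
gene subsets, group structures and coefficients simultaneously - mixes
integer, combinatorial and continuous optimisation and is intractable to
solve exactly at transcriptome scale.  The search therefore proceeds in the
staged Monte-Carlo fashion the objective was designed for:

1. draw many small gene sets from the screened candidates, fit a one-factor
   classifier per cohort, and *record* the genes of draws whose pooled
   sensitivity and specificity clear preset levels, tightening the levels
   until at most ``shrink_target`` genes remain;
2. draw multi-group partitions among the recorded genes, fit per-cohort
   competing factors for each, and keep the partition minimising the
   penalised objective (compared in the overflow-free log domain);
3. report the winner together with a checklist of the critical-gene
   criteria (gene-count cap, multi-cohort accuracy floors, a perfect
   cohort, sign consistency, per-cohort floors, and minimality metadata).

Coefficients for a fixed partition are fit by alternating hard assignment:
each tumor sample is assigned to its best-scoring factor, each factor is
refit as a smooth logistic surrogate on its assigned tumors versus all
controls, and an update is accepted only when the 0-1 count improves.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression

from .core import (
    INACTIVE,
    CohortDataset,
    CompetingFactor,
    GenePartition,
    MaxLogisticClassifier,
    PenaltyConfig,
    misclassification_count,
    penalized_objective,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConfig:
    """Search hyper-parameters.

    ``n_draws`` defaults to the published 50,000 random draws per stage;
    desk-scale runs use a few hundred to a few thousand.  ``sen_level`` /
    ``spe_level`` are the screening floors for recording a draw, raised by
    ``level_step`` whenever more than ``shrink_target`` genes are recorded.
    """

    G: int = 3
    group_size: int = 3
    n_draws: int = 50_000
    sen_level: float = 0.6
    spe_level: float = 0.90
    shrink_target: int = 30
    level_step: float = 0.05
    max_shrink_rounds: int = 8
    rng_seed: int = 0
    penalty: PenaltyConfig = field(default_factory=PenaltyConfig)
    max_refit_iter: int = 25
    surrogate_C: float = 1e4

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be at least 1")
        if self.group_size < 1 or self.G < 1:
            raise ValueError("group_size and G must be positive")
        for lvl in (self.sen_level, self.spe_level):
            if not (0.0 <= lvl < 1.0):
                raise ValueError("sen/spe levels must lie in [0, 1)")


@dataclass
class CriteriaReport:
    """Pass/fail evidence for the seven critical-gene criteria.

    Criteria 6 and 7 (minimal gene and factor counts) are tie-break
    metadata rather than pass/fail rules; ``passed`` covers criteria 1-5.
    """

    gene_count: int
    factor_count: int
    cap_ok: bool  # (1) union of at most 15 genes
    multi_cohort_ok: bool  # (2) >=95% accuracy in >=3 cohorts, >=1000 subjects
    perfect_cohort_ok: bool  # (3) 100% accuracy in a cohort of >=10 subjects
    sign_consistent_ok: bool  # (4) some gene keeps one sign wherever it appears
    per_cohort_floor_ok: bool  # (5) every cohort >=80% acc, sens or spec >75%
    evidence: dict = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return (
            self.cap_ok
            and self.multi_cohort_ok
            and self.perfect_cohort_ok
            and self.sign_consistent_ok
            and self.per_cohort_floor_ok
        )


# ---------------------------------------------------------------------------
# random draws
# ---------------------------------------------------------------------------


def random_subset_draw(
    candidates: Sequence[str],
    sizes: Sequence[int],
    rng: np.random.Generator,
) -> GenePartition:
    """Uniform without-replacement draw of each group; groups may overlap."""
    pool = sorted(candidates)
    if max(sizes) > len(pool):
        raise ValueError(
            f"cannot draw a group of {max(sizes)} from {len(pool)} candidates"
        )
    groups = []
    for size in sizes:
        idx = rng.choice(len(pool), size=size, replace=False)
        groups.append(tuple(pool[i] for i in sorted(idx)))
    return GenePartition(tuple(groups))


# ---------------------------------------------------------------------------
# coefficient fitting
# ---------------------------------------------------------------------------


def _fit_logistic(X: np.ndarray, y: np.ndarray, C: float) -> Tuple[float, np.ndarray]:
    model = LogisticRegression(C=C, solver="liblinear", max_iter=2000, random_state=0)
    model.fit(X, y)
    return float(model.intercept_[0]), model.coef_[0].astype(float)


def _cohort_fit(
    partition: GenePartition,
    cohort: CohortDataset,
    config: SearchConfig,
) -> List[CompetingFactor]:
    """Alternating hard-assignment fit of G factors on one cohort."""
    y = cohort.labels
    tumors = np.flatnonzero(y == 1)
    controls = np.flatnonzero(y == 0)
    if len(tumors) == 0 or len(controls) == 0:
        raise ValueError(f"cohort {cohort.cohort_id!r} has a single class")
    G = partition.G
    group_X = [cohort.gene_columns(genes) for genes in partition.groups]

    # initial hard assignment of tumors to factors: cluster the union-gene
    # profile (deterministic given the config seed)
    if G == 1:
        assign = np.zeros(len(tumors), dtype=int)
    else:
        union = sorted(partition.union)
        U = cohort.gene_columns(union)[tumors]
        sd = U.std(axis=0)
        U = (U - U.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        km = KMeans(n_clusters=min(G, len(tumors)), n_init=4,
                    random_state=config.rng_seed % (2**31))
        assign = km.fit_predict(U)

    def fit_round(assign: np.ndarray) -> List[CompetingFactor]:
        factors = []
        for j, genes in enumerate(partition.groups):
            mine = tumors[assign == j]
            if len(mine) == 0:
                factors.append(CompetingFactor.inactive(genes))
                continue
            rows = np.concatenate([mine, controls])
            Xj = group_X[j][rows]
            yj = y[rows]
            b0, beta = _fit_logistic(Xj, yj, config.surrogate_C)
            factors.append(CompetingFactor(b0, tuple(beta), tuple(genes)))
        return factors

    def scores_of(factors: List[CompetingFactor]) -> np.ndarray:
        out = np.empty((cohort.n_samples, G))
        for j, f in enumerate(factors):
            if not f.active:
                out[:, j] = INACTIVE
            else:
                out[:, j] = f.intercept + group_X[j] @ np.asarray(f.coefficients)
        return out

    def count_errors(scores: np.ndarray) -> int:
        m = scores.max(axis=1)
        return int(np.sum((m <= 0) & (y == 1)) + np.sum((m > 0) & (y == 0)))

    best_factors = fit_round(assign)
    scores = scores_of(best_factors)
    best_count = count_errors(scores)
    for _ in range(config.max_refit_iter):
        new_assign = scores[tumors].argmax(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        factors = fit_round(assign)
        scores = scores_of(factors)
        count = count_errors(scores)
        if count < best_count:  # accept only monotone improvements
            best_count, best_factors = count, factors
        else:
            break
    else:
        logger.warning(
            "coefficient fit on cohort %s did not converge in %d rounds; "
            "returning the best iterate",
            cohort.cohort_id,
            config.max_refit_iter,
        )
    return best_factors


def fit_coefficients(
    partition: GenePartition,
    cohorts: Sequence[CohortDataset],
    config: Optional[SearchConfig] = None,
) -> MaxLogisticClassifier:
    """Fit per-cohort competing factors for a fixed partition.

    Deterministic given the config seed; the accepted iterate never has a
    higher 0-1 count than the initial one.
    """
    config = config or SearchConfig()
    per_cohort = {c.cohort_id: _cohort_fit(partition, c, config) for c in cohorts}
    return MaxLogisticClassifier(partition, per_cohort)


# ---------------------------------------------------------------------------
# draw screening (computational steps 1-5)
# ---------------------------------------------------------------------------


def _pooled_sens_spec(classifier: MaxLogisticClassifier, cohorts) -> Tuple[float, float]:
    tp = fn = tn = fp = 0
    for c in cohorts:
        pred = classifier.predict(c)
        y = c.labels
        tp += int(np.sum((pred == 1) & (y == 1)))
        fn += int(np.sum((pred == 0) & (y == 1)))
        tn += int(np.sum((pred == 0) & (y == 0)))
        fp += int(np.sum((pred == 1) & (y == 0)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def screen_draws(
    candidates: Iterable[str],
    cohorts: Sequence[CohortDataset],
    config: Optional[SearchConfig] = None,
) -> Tuple[Set[str], List[dict]]:
    """Record genes of one-factor draws clearing the sen/spe levels.

    Implements the draw-record-shrink loop: if more than ``shrink_target``
    genes get recorded, the levels rise by ``level_step`` and drawing
    repeats among the recorded genes.  Returns the recorded set and a
    per-round trace.
    """
    config = config or SearchConfig()
    rng = np.random.default_rng(config.rng_seed % (2**31))
    pool = sorted(set(candidates))
    if not pool:
        raise ValueError("empty candidate set")
    sen, spe = config.sen_level, config.spe_level
    trace: List[dict] = []
    for round_no in range(config.max_shrink_rounds):
        recorded: Set[str] = set()
        size = min(config.group_size, len(pool))
        n_pass = 0
        for _ in range(config.n_draws):
            partition = random_subset_draw(pool, [size], rng)
            clf = fit_coefficients(partition, cohorts, config)
            sens, spec = _pooled_sens_spec(clf, cohorts)
            if sens > sen and spec > spe:
                recorded |= set(partition.groups[0])
                n_pass += 1
        trace.append(
            {"round": round_no, "sen": sen, "spe": spe, "pool": len(pool),
             "passing_draws": n_pass, "recorded": len(recorded)}
        )
        if not recorded:
            logger.warning(
                "no draw cleared sen=%.2f / spe=%.2f; returning an empty record "
                "(consider lowering the levels)", sen, spe,
            )
            return set(), trace
        if len(recorded) <= config.shrink_target:
            return recorded, trace
        pool = sorted(recorded)
        sen = min(sen + config.level_step, 0.99)
        spe = min(spe + config.level_step, 0.99)
    return recorded, trace


# ---------------------------------------------------------------------------
# final search (steps 6-7) and criteria
# ---------------------------------------------------------------------------


def _evaluate_partition(partition, cohorts, config) -> Tuple[float, MaxLogisticClassifier]:
    clf = fit_coefficients(partition, cohorts, config)
    return penalized_objective(clf, cohorts, config.penalty, form="log"), clf


def _candidate_partitions_random(pool, config, rng) -> Iterable[GenePartition]:
    for G in range(1, config.G + 1):
        sizes = [min(config.group_size, len(pool))] * G
        for _ in range(config.n_draws):
            yield random_subset_draw(pool, sizes, rng)


def monte_carlo_search(
    cohorts: Sequence[CohortDataset],
    config: Optional[SearchConfig] = None,
    candidates: Optional[Iterable[str]] = None,
) -> Tuple[MaxLogisticClassifier, CriteriaReport, dict]:
    """Full staged search: draw screening, then penalised partition search.

    ``candidates`` is the screened gene pool (e.g. the MVS-CGS output); when
    omitted, every shared gene is eligible.  Ties in the objective resolve
    to the earliest draw.  Returns (best classifier, criteria report, trace).
    """
    config = config or SearchConfig()
    if not cohorts:
        raise ValueError("at least one cohort is required")
    if candidates is None:
        shared = set(cohorts[0].gene_ids)
        for c in cohorts[1:]:
            shared &= set(c.gene_ids)
        candidates = shared
    recorded, screen_trace = screen_draws(candidates, cohorts, config)
    if not recorded:
        logger.warning("draw screening recorded nothing; searching the raw candidates")
        recorded = set(candidates)
    rng = np.random.default_rng((config.rng_seed + 1) % (2**31))
    pool = sorted(recorded)

    best = None
    seen = set()
    n_evaluated = 0
    for partition in _candidate_partitions_random(pool, config, rng):
        key = partition.canonical()
        if key in seen:
            continue
        seen.add(key)
        obj, clf = _evaluate_partition(partition, cohorts, config)
        n_evaluated += 1
        if best is None or obj < best[0]:
            best = (obj, clf)
    assert best is not None
    obj, clf = best
    report = criteria_from_classifier(clf, cohorts)
    trace = {
        "screen": screen_trace,
        "recorded_genes": pool,
        "evaluated_partitions": n_evaluated,
        "best_objective_log": obj,
    }
    logger.info(
        "search finished: %d distinct partitions, best log-objective %.4f, union %s",
        n_evaluated, obj, sorted(clf.partition.union),
    )
    return clf, report, trace


def exhaustive_search(
    candidates: Iterable[str],
    cohorts: Sequence[CohortDataset],
    config: Optional[SearchConfig] = None,
) -> Tuple[MaxLogisticClassifier, float]:
    """Enumerate every partition with G <= config.G groups of exactly
    ``group_size`` genes (tiny pools only) and return the objective minimiser.

    This is the enumeration reference the Monte-Carlo search is validated
    against on instances small enough to enumerate.
    """
    config = config or SearchConfig()
    pool = sorted(set(candidates))
    size = min(config.group_size, len(pool))
    groups = list(itertools.combinations(pool, size))
    best = None
    for G in range(1, config.G + 1):
        for combo in itertools.combinations_with_replacement(range(len(groups)), G):
            partition = GenePartition(tuple(groups[i] for i in combo))
            obj, clf = _evaluate_partition(partition, cohorts, config)
            if best is None or obj < best[0]:
                best = (obj, clf)
    assert best is not None
    return best[1], best[0]


# ---------------------------------------------------------------------------
# the seven criteria
# ---------------------------------------------------------------------------


def _sign_consistency(classifier: MaxLogisticClassifier) -> Dict[str, bool]:
    """Per-gene flag: does the gene keep one sign in every cohort it serves?"""
    signs: Dict[str, Set[float]] = {}
    for factors in classifier.per_cohort_factors.values():
        for f in factors:
            if not f.active:
                continue
            for g, c in zip(f.genes, f.coefficients):
                if c != 0.0:
                    signs.setdefault(g, set()).add(np.sign(c))
    return {g: len(s) == 1 for g, s in signs.items()}


def check_critical_criteria(
    per_cohort_reports: Sequence[dict],
    partition: GenePartition,
    classifier: Optional[MaxLogisticClassifier] = None,
) -> CriteriaReport:
    """Evaluate the seven critical-gene rules.

    Each report dict carries ``cohort_id``, ``n`` (subjects), ``accuracy``,
    ``sensitivity``, ``specificity`` in percent.  Sign consistency needs the
    classifier; without one it is vacuously false.
    """
    if not per_cohort_reports:
        raise ValueError("at least one cohort report is required")
    gene_count = len(partition.union)
    factor_count = partition.G

    cap_ok = gene_count <= 15

    high = [r for r in per_cohort_reports if r["accuracy"] >= 95.0]
    multi_ok = len(high) >= 3 and sum(r["n"] for r in high) >= 1000

    perfect_ok = any(r["accuracy"] == 100.0 and r["n"] >= 10 for r in per_cohort_reports)

    consistency = _sign_consistency(classifier) if classifier is not None else {}
    sign_ok = any(consistency.values())

    floor_ok = all(
        r["accuracy"] >= 80.0
        and ((r["sensitivity"] or 0) > 75.0 or (r["specificity"] or 0) > 75.0)
        for r in per_cohort_reports
    )

    return CriteriaReport(
        gene_count=gene_count,
        factor_count=factor_count,
        cap_ok=cap_ok,
        multi_cohort_ok=multi_ok,
        perfect_cohort_ok=perfect_ok,
        sign_consistent_ok=sign_ok,
        per_cohort_floor_ok=floor_ok,
        evidence={
            "high_accuracy_cohorts": [r["cohort_id"] for r in high],
            "high_accuracy_subjects": sum(r["n"] for r in high),
            "sign_consistency": consistency,
            "per_cohort": list(per_cohort_reports),
        },
    )


def criteria_from_classifier(
    classifier: MaxLogisticClassifier, cohorts: Sequence[CohortDataset]
) -> CriteriaReport:
    """Criteria report computed directly from a classifier on its cohorts."""
    from .evaluation import confusion_metrics  # local import to avoid a cycle

    reports = []
    for c in cohorts:
        m = confusion_metrics(classifier.predict(c), c.labels)
        reports.append(
            {
                "cohort_id": c.cohort_id,
                "n": c.n_samples,
                "accuracy": m.accuracy,
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
            }
        )
    return check_critical_criteria(reports, classifier.partition, classifier)
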