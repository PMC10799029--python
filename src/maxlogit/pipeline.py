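"""End-to-end orchestration and reproducibility experiments.

`run_pipeline` chains screening -> search -> evaluation on a list of
cohorts and persists every intermediate artifact plus a manifest (config
hash, seed, library versions).  The two experiment helpers re-run the
search under controlled conditions: against exhaustive enumeration on
instances small enough to enumerate, and against the synthetic generator's
planted truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .core import CohortDataset, PenaltyConfig
from .evaluation import evaluate_cohort, metrics_table, risk_table, subgroup_table
from .io import save_classifier
from .screening import ScreeningConfig, screen_cohorts
from .search import SearchConfig, exhaustive_search, fit_coefficients, monte_carlo_search

logger = logging.getLogger(__name__)

#: Desk-scale search settings: a few hundred draws per stage suffice for
#: candidate pools of a few dozen genes and keep a full multi-cohort run in
#: the seconds range.
DESK_SEARCH = dict(G=2, group_size=2, n_draws=300, shrink_target=30)


def _config_hash(*configs) -> str:
    blob = json.dumps([asdict(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(out_dir: Path, seed: int, *configs) -> Path:
    import pandas
    import scipy
    import sklearn

    manifest = {
        "package": f"maxlogit {__version__}",
        "config_hash": _config_hash(*configs),
        "seed": seed,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def run_pipeline(
    cohorts: Sequence[CohortDataset],
    out_dir,
    screening_config: Optional[ScreeningConfig] = None,
    search_config: Optional[SearchConfig] = None,
) -> dict:
    """screen -> search -> evaluate, artifacts persisted under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    screening_config = screening_config or ScreeningConfig()
    search_config = search_config or SearchConfig(**DESK_SEARCH)

    candidates = screen_cohorts(cohorts, screening_config)
    logger.info("screening kept %d candidate genes", len(candidates))
    (out_dir / "candidates.txt").write_text("\n".join(sorted(candidates)) + "\n")
    if not candidates:
        raise RuntimeError("screening produced no candidate genes")

    classifier, criteria, trace = monte_carlo_search(cohorts, search_config, candidates)
    save_classifier(classifier, out_dir / "classifier.json")
    (out_dir / "search_trace.json").write_text(json.dumps(trace, indent=1, default=str))

    per_cohort = {c.cohort_id: evaluate_cohort(classifier, c) for c in cohorts}
    metrics_table(per_cohort).to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    for c in cohorts:
        subgroup_table(classifier, c).to_csv(
            out_dir / f"{c.cohort_id}.subgroups.tsv", sep="\t", index=False
        )
        risk_table(classifier, c).to_csv(
            out_dir / f"{c.cohort_id}.risk.tsv", sep="\t", index=False
        )
    criteria_doc = {
        "gene_count": criteria.gene_count,
        "factor_count": criteria.factor_count,
        "cap_ok": criteria.cap_ok,
        "multi_cohort_ok": criteria.multi_cohort_ok,
        "perfect_cohort_ok": criteria.perfect_cohort_ok,
        "sign_consistent_ok": criteria.sign_consistent_ok,
        "per_cohort_floor_ok": criteria.per_cohort_floor_ok,
        "passed": criteria.passed,
    }
    (out_dir / "criteria.json").write_text(json.dumps(criteria_doc, indent=1))
    write_manifest(out_dir, search_config.rng_seed, screening_config, search_config)
    return {
        "candidates": candidates,
        "classifier": classifier,
        "criteria": criteria,
        "per_cohort": per_cohort,
        "trace": trace,
    }


# ---------------------------------------------------------------------------
# controlled experiments
# ---------------------------------------------------------------------------


def oracle_equivalence_experiment(
    n_runs: int = 20,
    seed: int = 1,
    n_candidate_genes: int = 6,
    n_per_cohort: int = 60,
) -> dict:
    """Monte-Carlo search versus exhaustive enumeration on tiny instances.

    Each run plants a 2-factor rule among ``n_candidate_genes`` genes in two
    small cohorts, runs both searches over all partitions with at most two
    groups of two genes, and compares the attained objectives.
    """
    from .simulate import SimulationConfig, generate_multicohort

    hits = 0
    for r in range(n_runs):
        sim = SimulationConfig(
            K=2,
            n_per_cohort=n_per_cohort,
            n_genes=n_candidate_genes,
            seed=(seed + 7919 * r) % (2**31),
        )
        cohorts = [c for c, _ in generate_multicohort(sim)]
        config = SearchConfig(
            G=2, group_size=2, n_draws=250, sen_level=0.0, spe_level=0.0,
            rng_seed=(seed + r) % (2**31),
        )
        genes = list(cohorts[0].gene_ids)
        mc_clf, _, _ = monte_carlo_search(cohorts, config, genes)
        ex_clf, ex_obj = exhaustive_search(genes, cohorts, config)
        from .core import penalized_objective

        mc_obj = penalized_objective(mc_clf, cohorts, config.penalty, form="log")
        if mc_obj <= ex_obj + 1e-9:
            hits += 1
    return {"runs": n_runs, "hits": hits, "rate": hits / n_runs}


def planted_recovery_experiment(
    n_runs: int = 20,
    seed: int = 1,
    sim_overrides: Optional[dict] = None,
) -> dict:
    """Recover the planted causal genes through the full pipeline.

    Each run generates the default three-cohort benchmark (4 causal genes
    among 200, two planted factors, 500 samples per cohort), screens,
    searches, and checks how much of the causal union the winning partition
    recovers and how accurate the classifier is per cohort.
    """
    from .simulate import SimulationConfig, generate_multicohort

    recoveries: List[int] = []
    accuracies: List[float] = []
    for r in range(n_runs):
        sim = SimulationConfig(
            seed=(seed + 104729 * r) % (2**31), **(sim_overrides or {})
        )
        pairs = generate_multicohort(sim)
        cohorts = [c for c, _ in pairs]
        truth = pairs[0][1]
        candidates = screen_cohorts(cohorts)
        if not candidates:
            recoveries.append(0)
            continue
        config = SearchConfig(rng_seed=(seed + r) % (2**31), **DESK_SEARCH)
        classifier, _, _ = monte_carlo_search(cohorts, config, candidates)
        union = classifier.partition.union
        recoveries.append(len(union & set(truth.causal_genes)))
        for c in cohorts:
            m = evaluate_cohort(classifier, c)
            accuracies.append(m.accuracy)
    recovered = sum(1 for r_ in recoveries if r_ >= 3)
    return {
        "runs": n_runs,
        "recovered_runs": recovered,
        "rate": recovered / n_runs,
        "recovered_causal_counts": recoveries,
        "min_cohort_accuracy": min(accuracies) if accuracies else float("nan"),
        "mean_cohort_accuracy": float(np.mean(accuracies)) if accuracies else float("nan"),
    }
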