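import numpy as np
import pytest

import maxlogit as ml


@pytest.fixture(scope="session")
def published_classifiers():
    return ml.load_published("table2")


@pytest.fixture(scope="session")
def worked_examples():
    return ml.load_published("table3")


@pytest.fixture(scope="session")
def small_pairs():
    """Two small planted cohorts (fast, shared across read-only tests)."""
    sim = ml.SimulationConfig(K=2, n_per_cohort=150, n_genes=60, seed=11)
    return sim, ml.generate_multicohort(sim)


@pytest.fixture(scope="session")
def small_cohorts(small_pairs):
    _, pairs = small_pairs
    return [c for c, _ in pairs]


def toy_cohort(expression, labels, cohort_id="toy", gene_ids=None, **kw):
    expression = np.asarray(expression, dtype=float)
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(expression.shape[1])]
    return ml.CohortDataset(cohort_id, expression, np.asarray(labels), gene_ids, **kw)
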