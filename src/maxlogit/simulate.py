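"""Multi-cohort synthetic expression data with a planted max-logistic rule.

The generator emulates the statistical structure the analysis consumes: K
cohorts on different measurement scales (log-count-like, array-intensity-
like, RT-PCR-like) sharing a small causal gene set whose labels follow a
planted max-of-linear-predictors rule, buried among exchangeable null
genes.

Geometry (latent scale).  Controls sit at the origin of the causal
subspace.  Tumors belong to one of two subtypes; a subtype elevates the
genes of its own planted group strongly (``delta_high``) and the other
group's genes mildly (``delta_low``).  Each planted factor is the
mid-plane discriminant of its subtype against controls, scaled so controls
score ``-margin`` and own-subtype tumors ``+margin``.  Because every causal
gene is elevated in all tumors, each passes marginal screening, while small
gene subsets still confuse part of the opposite subtype - so the selection
objective genuinely needs most of the causal union.

Each cohort applies a positive affine map per platform tag to the causal
latent values, and draws null genes from a platform-specific baseline.  The
planted factors are exported on the cohort's native scale, so the planted
classifier reproduces the planted log-odds exactly on its own data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import expit

from .core import CohortDataset, CompetingFactor, GenePartition, MaxLogisticClassifier

#: Positive affine map (scale, offset) from latent units to the native scale,
#: and the null-gene baseline sampler, per platform tag.
PLATFORM_PARAMS: Dict[str, Tuple[float, float]] = {
    "log-count": (1.0, 8.0),
    "intensity": (120.0, 500.0),
    "pcr-like": (2.0, 5.0),
}


def _null_baseline(tag: str, rng: np.random.Generator, size) -> np.ndarray:
    if tag == "log-count":
        return np.clip(rng.normal(8.0, 1.5, size), 0.0, None)
    if tag == "intensity":
        return rng.gamma(2.0, 250.0, size)
    if tag == "pcr-like":
        return rng.lognormal(0.5, 0.8, size)
    raise ValueError(f"unknown platform tag {tag!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic multi-cohort benchmark.

    Defaults plant 4 causal genes (two groups of two) among 200 genes in
    K = 3 cohorts of 500 samples each at 50% tumor prevalence, with platform
    tags cycling through the three measurement scales.
    """

    K: int = 3
    n_per_cohort: int = 500
    n_genes: int = 200
    n_causal: int = 4
    causal_genes: Optional[Tuple[str, ...]] = None
    group_sizes: Tuple[int, ...] = (2, 2)
    prevalence: float = 0.5
    subtype_fractions: Tuple[float, ...] = (0.5, 0.5)
    platforms: Tuple[str, ...] = ("log-count", "intensity", "pcr-like")
    delta_high: float = 3.0
    delta_low: float = 2.0
    noise_sd: float = 1.0
    control_sd: float = 0.5
    margin: float = 6.0
    label_mode: str = "deterministic"
    sign_flips: Tuple[Tuple[int, str], ...] = ()
    with_strata: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must lie in (0, 1)")
        if self.noise_sd < 0 or self.control_sd < 0:
            raise ValueError("noise_sd and control_sd must be non-negative")
        if self.label_mode not in ("deterministic", "bernoulli"):
            raise ValueError("label_mode must be 'deterministic' or 'bernoulli'")
        if sum(self.group_sizes) != self.n_causal:
            raise ValueError("group sizes must sum to the causal gene count")
        if abs(sum(self.subtype_fractions) - 1.0) > 1e-12:
            raise ValueError("subtype fractions must sum to 1")
        if len(self.subtype_fractions) != len(self.group_sizes):
            raise ValueError("one subtype per planted group")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.label_mode == "deterministic" and self.prevalence * self.n_per_cohort < 1:
            raise ValueError(
                "infeasible prevalence: fewer than one expected tumor per cohort"
            )

    def gene_universe(self) -> List[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def resolved_causal_genes(self) -> Tuple[str, ...]:
        if self.causal_genes is not None:
            return tuple(self.causal_genes)
        # deterministic, evenly spread positions in the universe
        universe = self.gene_universe()
        step = max(1, self.n_genes // (self.n_causal + 1))
        return tuple(universe[(i + 1) * step - 1] for i in range(self.n_causal))

    def planted_partition(self) -> GenePartition:
        causal = self.resolved_causal_genes()
        groups, start = [], 0
        for size in self.group_sizes:
            groups.append(tuple(causal[start : start + size]))
            start += size
        return GenePartition(tuple(groups))


@dataclass
class PlantedTruth:
    """Ground truth stored alongside a generated cohort."""

    causal_genes: Tuple[str, ...]
    partition: GenePartition
    factors: List[CompetingFactor]  # native scale
    logodds: np.ndarray
    labels: np.ndarray
    components: np.ndarray  # 0 = control-like, 1.. = tumor subtype

    def classifier(self, cohort_id: str) -> MaxLogisticClassifier:
        return MaxLogisticClassifier(self.partition, {cohort_id: list(self.factors)})


def _latent_means(config: SimulationConfig, cohort_index: int) -> np.ndarray:
    """(n_components+1, n_causal) latent mean matrix; row 0 is controls."""
    causal = config.resolved_causal_genes()
    n_sub = len(config.group_sizes)
    means = np.zeros((n_sub + 1, config.n_causal))
    start = 0
    group_slices = []
    for size in config.group_sizes:
        group_slices.append(slice(start, start + size))
        start += size
    for z, sl in enumerate(group_slices, start=1):
        means[z, :] = config.delta_low
        means[z, sl] = config.delta_high
    for k_flip, gene in config.sign_flips:
        if k_flip == cohort_index:
            g_idx = causal.index(gene)
            means[1:, g_idx] *= -1.0
    return means


def _planted_factors_latent(config: SimulationConfig, cohort_index: int) -> List[Tuple[float, np.ndarray]]:
    """Mid-plane discriminants in latent units: (intercept, coefs over own group)."""
    means = _latent_means(config, cohort_index)
    factors = []
    start = 0
    for z, size in enumerate(config.group_sizes, start=1):
        mu = means[z, start : start + size]  # own-group elevation (possibly flipped)
        norm2 = float(mu @ mu)
        if norm2 == 0.0:  # signal-free configuration: a constant -margin factor
            factors.append((-config.margin, np.zeros(size)))
        else:
            alpha = 2.0 * config.margin / norm2
            factors.append((-config.margin, alpha * mu))
        start += size
    return factors


def generate_cohort(config: SimulationConfig, cohort_index: int) -> Tuple[CohortDataset, PlantedTruth]:
    """Generate one cohort and its planted truth; reproducible from the seed.

    The causal latent draw and component assignment depend only on
    (seed, cohort_index), so cohorts that differ only in platform tag carry
    identical labels and monotonically related causal columns.
    """
    if not (0 <= cohort_index < config.K):
        raise ValueError(f"cohort_index must lie in [0, {config.K})")
    rng = np.random.default_rng([config.seed % (2**31), cohort_index])
    universe = config.gene_universe()
    causal = config.resolved_causal_genes()
    causal_idx = [universe.index(g) for g in causal]
    n = config.n_per_cohort
    n_sub = len(config.group_sizes)

    probs = [1.0 - config.prevalence] + [
        config.prevalence * f for f in config.subtype_fractions
    ]
    components = rng.choice(np.arange(n_sub + 1), size=n, p=probs)
    means = _latent_means(config, cohort_index)
    sd = np.where(components == 0, config.control_sd, config.noise_sd)
    latent = means[components] + sd[:, None] * rng.standard_normal((n, config.n_causal))

    # planted scoring in latent units
    factors_latent = _planted_factors_latent(config, cohort_index)
    partition = config.planted_partition()
    scores = np.empty((n, n_sub))
    start = 0
    for j, (b0, beta) in enumerate(factors_latent):
        size = len(beta)
        scores[:, j] = b0 + latent[:, start : start + size] @ beta
        start += size
    logodds = scores.max(axis=1)
    if config.label_mode == "deterministic":
        labels = (logodds > 0).astype(int)
    else:
        labels = rng.binomial(1, expit(logodds))
    if labels.min() == labels.max():
        raise ValueError(
            "degenerate draw: only one class realised; prevalence/margin infeasible"
        )

    # assemble the native-scale matrix (null draws happen after labelling so
    # the platform never touches the labels)
    tag = config.platforms[cohort_index % len(config.platforms)]
    if tag not in PLATFORM_PARAMS:
        raise ValueError(f"unknown platform tag {tag!r}; choose from {sorted(PLATFORM_PARAMS)}")
    scale, offset = PLATFORM_PARAMS[tag]
    expression = _null_baseline(tag, rng, (n, config.n_genes))
    expression[:, causal_idx] = scale * latent + offset

    # planted factors mapped to the native scale: x_native = scale*x + offset
    native_factors = []
    start = 0
    for (b0, beta), genes in zip(factors_latent, partition.groups):
        beta_native = beta / scale
        b0_native = b0 - float(beta_native.sum()) * offset
        native_factors.append(
            CompetingFactor(b0_native, tuple(beta_native), tuple(genes))
        )
        start += len(beta)

    strata = None
    if config.with_strata:
        strata = rng.choice([f"CMS{i}" for i in range(1, 5)], size=n)

    cohort_id = f"cohort{cohort_index + 1}-{tag}"
    cohort = CohortDataset(
        cohort_id=cohort_id,
        expression=expression,
        labels=labels,
        gene_ids=universe,
        strata=strata,
    )
    truth = PlantedTruth(
        causal_genes=causal,
        partition=partition,
        factors=native_factors,
        logodds=logodds,
        labels=labels.copy(),
        components=components,
    )
    return cohort, truth


def generate_multicohort(config: SimulationConfig) -> List[Tuple[CohortDataset, PlantedTruth]]:
    """K cohorts sharing causal genes and partition, platforms cycling."""
    return [generate_cohort(config, k) for k in range(config.K)]


def planted_classifier(config: SimulationConfig, cohorts_truths) -> MaxLogisticClassifier:
    """Bundle the per-cohort planted factors into one classifier."""
    partition = config.planted_partition()
    per_cohort = {
        cohort.cohort_id: list(truth.factors) for cohort, truth in cohorts_truths
    }
    return MaxLogisticClassifier(partition, per_cohort)


def null_config(config: SimulationConfig) -> SimulationConfig:
    """Same conditions with the causal signal removed (labels random)."""
    return replace(
        config,
        delta_high=0.0,
        delta_low=0.0,
        label_mode="bernoulli",
        margin=1e-9,
    )
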