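"""Published four-gene classifiers and worked examples, with self-checks.

Ships the reported classifier coefficients for the ten CRC study cohorts
and the per-sample worked-example rows (expression values, competing-factor
scores, winning score and risk probability, exactly as printed), and
verifies this package's scoring against them:

(a) the maximum of the printed factor scores equals the printed winning
    score exactly;
(b) the logistic transform of the printed winning score reproduces the
    printed risk probability at its displayed precision (allowing for the
    display rounding of the winning score itself);
(c) where the gene-column assignment is explicit, re-scoring the printed
    expression values with the published coefficients lands within 0.05 of
    the printed factor score (the slack display-rounded inputs admit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import CompetingFactor, GenePartition, MaxLogisticClassifier, risk_probability

GENE_COLUMNS = ("APP", "CXCL8", "PSMC2", "SLC20A1")

#: |recomputed - printed| tolerance for check (c): expression is printed at
#: 2 decimals and coefficients at 4, so the recomputed score can drift by a
#: few hundredths.
CHECK_C_TOL = 0.05


@dataclass(frozen=True)
class PublishedFactor:
    name: str
    intercept: float
    genes: Tuple[str, ...]
    coefficients: Tuple[float, ...]
    assignment: str  # "explicit" | "inferred"
    accuracy: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None

    def as_competing_factor(self) -> CompetingFactor:
        return CompetingFactor(self.intercept, self.coefficients, self.genes)


@dataclass(frozen=True)
class PublishedDataset:
    dataset: int
    source: str
    n_tumor: int
    n_normal: int
    factors: Tuple[PublishedFactor, ...]
    max_metrics: Optional[dict]
    stage1_factor: Optional[PublishedFactor]
    note: str = ""

    @property
    def n(self) -> int:
        return self.n_tumor + self.n_normal

    def main_factors(self) -> Tuple[PublishedFactor, ...]:
        """The competing factors of the combined classifier (the stage-1
        single-gene factor stands in where it is the only classifier)."""
        if self.factors:
            return self.factors
        if self.stage1_factor is not None:
            return (self.stage1_factor,)
        raise ValueError(f"dataset {self.dataset} carries no factors")

    def classifier(self) -> MaxLogisticClassifier:
        factors = [f.as_competing_factor() for f in self.main_factors()]
        partition = GenePartition(tuple(f.genes for f in factors))
        return MaxLogisticClassifier(partition, {self.source: factors})

    def combined_metrics(self) -> dict:
        """Reported performance of the combined (max) classifier."""
        if self.max_metrics is not None:
            return dict(self.max_metrics)
        only = self.main_factors()[0]
        return {
            "accuracy": only.accuracy,
            "sensitivity": only.sensitivity,
            "specificity": only.specificity,
        }


@dataclass(frozen=True)
class WorkedExampleRow:
    """One printed sample row; printed numbers kept as strings to preserve
    the displayed precision."""

    dataset: int
    sample_id: str
    label: int
    expression: Dict[str, float]
    cf_printed: Tuple[str, ...]
    cf_max_printed: str
    p_max_printed: str

    @property
    def cf_values(self) -> Tuple[float, ...]:
        return tuple(float(s) for s in self.cf_printed)

    @property
    def cf_max(self) -> float:
        return float(self.cf_max_printed)

    @property
    def p_max(self) -> float:
        return float(self.p_max_printed)


class PublishedClassifierSet:
    def __init__(self, datasets: Dict[int, PublishedDataset]):
        self.datasets = datasets

    def __getitem__(self, dataset: int) -> PublishedDataset:
        return self.datasets[dataset]

    def __iter__(self):
        return iter(self.datasets.values())

    def all_factors(self):
        for ds in self:
            yield from ds.factors
            if ds.stage1_factor is not None:
                yield ds.stage1_factor


def _read_packaged(name: str) -> dict:
    with resources.files("maxlogit.data").joinpath(name).open() as fh:
        return json.load(fh)


def _parse_factor(doc: Optional[dict]) -> Optional[PublishedFactor]:
    if doc is None:
        return None
    return PublishedFactor(
        name=doc["name"],
        intercept=float(doc["intercept"]),
        genes=tuple(doc["genes"]),
        coefficients=tuple(float(c) for c in doc["coefficients"]),
        assignment=doc["assignment"],
        accuracy=doc.get("accuracy"),
        sensitivity=doc.get("sensitivity"),
        specificity=doc.get("specificity"),
    )


def load_published(fixture_id: str):
    """Load a packaged fixture: 'table2' (classifiers) or 'table3' (rows)."""
    if fixture_id in ("table2", "classifiers"):
        doc = _read_packaged("published_classifiers.json")
        if doc.get("format") != "maxlogit-published-classifiers-v1":
            raise ValueError("corrupt published-classifier fixture")
        datasets = {}
        for entry in doc["datasets"]:
            ds = PublishedDataset(
                dataset=int(entry["dataset"]),
                source=entry["source"],
                n_tumor=int(entry["n_tumor"]),
                n_normal=int(entry["n_normal"]),
                factors=tuple(_parse_factor(f) for f in entry["factors"]),
                max_metrics=entry.get("max_metrics"),
                stage1_factor=_parse_factor(entry.get("stage1_factor")),
                note=entry.get("note", ""),
            )
            datasets[ds.dataset] = ds
        return PublishedClassifierSet(datasets)
    if fixture_id in ("table3", "worked_examples"):
        doc = _read_packaged("worked_examples.json")
        if doc.get("format") != "maxlogit-worked-examples-v1":
            raise ValueError("corrupt worked-example fixture")
        rows: List[WorkedExampleRow] = []
        for block in doc["blocks"]:
            for r in block["rows"]:
                rows.append(
                    WorkedExampleRow(
                        dataset=int(block["dataset"]),
                        sample_id=r["sample_id"],
                        label=int(r["label"]),
                        expression={g: float(v) for g, v in r["expression"].items()},
                        cf_printed=tuple(s for s in r["cf"] if s is not None),
                        cf_max_printed=r["cf_max"],
                        p_max_printed=r["p_max"],
                    )
                )
        return rows
    raise ValueError(f"unknown fixture {fixture_id!r}; use 'table2' or 'table3'")


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------


def _ulp(printed: str) -> float:
    """One unit in the last displayed place of a printed number."""
    s = printed.strip().upper()
    exp = 0
    if "E" in s:
        s, e = s.split("E")
        exp = int(e)
    decimals = len(s.split(".")[1]) if "." in s else 0
    return 10.0 ** (exp - decimals)


def verify_worked_examples(
    rows: Optional[List[WorkedExampleRow]] = None,
    classifiers: Optional[PublishedClassifierSet] = None,
) -> pd.DataFrame:
    """Run checks (a)-(c) on every worked-example row.

    Check (b) passes when |logistic(cf_max) - p_max| stays within half a
    display unit of the printed probability plus the propagated half-unit
    rounding of the printed winning score (derivative p(1-p)).  Check (c)
    runs only where every factor assignment of the row's dataset is
    explicit; elsewhere it reports no verdict.
    """
    rows = rows if rows is not None else load_published("table3")
    classifiers = classifiers if classifiers is not None else load_published("table2")
    records = []
    for row in rows:
        cfs = row.cf_values
        check_a = max(cfs) == row.cf_max

        p = risk_probability(row.cf_max)
        tol_b = 0.5 * _ulp(row.p_max_printed) + p * (1 - p) * 0.5 * _ulp(row.cf_max_printed)
        check_b = abs(p - row.p_max) <= tol_b

        ds = classifiers[row.dataset]
        factors = ds.main_factors()
        check_c: Optional[bool] = None
        max_dev = None
        if all(f.assignment == "explicit" for f in factors) and len(factors) == len(cfs):
            devs = []
            for f, printed in zip(factors, cfs):
                x = np.array([row.expression[g] for g in f.genes])
                score = f.intercept + float(x @ np.asarray(f.coefficients))
                devs.append(abs(score - printed))
            max_dev = max(devs)
            check_c = max_dev <= CHECK_C_TOL
        records.append(
            {
                "dataset": row.dataset,
                "sample_id": row.sample_id,
                "check_a": check_a,
                "check_b": check_b,
                "check_c": check_c,
                "p_recomputed": p,
                "cf_max_deviation": max_dev,
            }
        )
    return pd.DataFrame(records)


def coefficient_sign_table(classifiers: Optional[PublishedClassifierSet] = None) -> pd.DataFrame:
    """Signs of every published coefficient, one row per (dataset, factor, gene)."""
    classifiers = classifiers if classifiers is not None else load_published("table2")
    rows = []
    for ds in classifiers:
        for f in list(ds.factors) + ([ds.stage1_factor] if ds.stage1_factor else []):
            for g, c in zip(f.genes, f.coefficients):
                rows.append(
                    {"dataset": ds.dataset, "factor": f.name, "gene": g,
                     "coefficient": c, "sign": int(np.sign(c))}
                )
    return pd.DataFrame(rows)
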