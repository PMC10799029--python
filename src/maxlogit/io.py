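"""Delimited-text ingest and classifier serialization.

Expression tables are TSV/CSV with a header line, in either orientation
(genes-in-rows with sample ids in the header, or samples-in-rows with gene
ids in the header).  Labels are a two-column sample -> {0,1} table.  The
optional per-cohort transform (natural log, or log2(x+1)) mirrors the
per-platform preprocessing commonly applied to public expression matrices
and is applied before any statistic.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CohortDataset, CompetingFactor, GenePartition, MaxLogisticClassifier

TRANSFORMS = ("none", "natural-log", "log2-plus-1")


def _apply_transform(frame: pd.DataFrame, transform: Optional[str]) -> pd.DataFrame:
    if transform in (None, "none"):
        return frame
    if transform == "natural-log":
        if (frame.values <= 0).any():
            raise ValueError("natural-log transform requires strictly positive values")
        return np.log(frame)
    if transform == "log2-plus-1":
        if (frame.values < 0).any():
            raise ValueError("log2-plus-1 transform requires non-negative values")
        return np.log2(frame + 1.0)
    raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")


def _detect_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path,
    orientation: str = "genes_in_rows",
    transform: Optional[str] = None,
    uppercase_genes: bool = True,
) -> pd.DataFrame:
    """Read a delimited expression table into a samples x genes DataFrame.

    Raises on ragged rows, duplicate gene identifiers and non-numeric cells,
    naming the offender.
    """
    path = Path(path)
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError("orientation must be 'genes_in_rows' or 'samples_in_rows'")
    try:
        frame = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    if frame.empty:
        raise ValueError(f"empty expression table: {path}")
    bad = frame.columns[frame.dtypes == object]
    for col in bad:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric cell in column {col!r} of {path}: {exc}") from exc
    if frame.isna().any().any():
        raise ValueError(f"missing values in expression table {path}")
    if orientation == "genes_in_rows":
        frame = frame.T
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if uppercase_genes:
        frame.columns = [c.upper() for c in frame.columns]
    dup = pd.Index(frame.columns)[pd.Index(frame.columns).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene identifiers in {path}: {sorted(set(dup))}")
    return _apply_transform(frame.astype(float), transform)


def read_labels(path) -> pd.Series:
    """Two-column sample -> {0,1} table."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_detect_sep(path), index_col=0)
    if frame.shape[1] != 1:
        raise ValueError(f"label table {path} must have exactly two columns")
    series = frame.iloc[:, 0].astype(int)
    series.index = series.index.astype(str)
    if not series.isin((0, 1)).all():
        raise ValueError(f"labels in {path} must be 0 or 1")
    return series


def load_cohort(
    expression_path,
    labels_path,
    cohort_id: Optional[str] = None,
    orientation: str = "genes_in_rows",
    transform: Optional[str] = None,
    strata_path=None,
) -> CohortDataset:
    """Assemble a CohortDataset from expression + label (+ strata) tables."""
    expr = read_expression_table(expression_path, orientation, transform)
    labels = read_labels(labels_path)
    missing = [s for s in expr.index if s not in labels.index]
    if missing:
        raise ValueError(f"samples without labels: {missing[:5]}")
    labels = labels.loc[expr.index]
    strata = None
    if strata_path is not None:
        sf = pd.read_csv(Path(strata_path), sep=_detect_sep(Path(strata_path)), index_col=0)
        strata = sf.iloc[:, 0].astype(str).loc[expr.index].to_numpy()
    return CohortDataset(
        cohort_id=cohort_id or Path(expression_path).stem,
        expression=expr.to_numpy(),
        labels=labels.to_numpy(),
        gene_ids=list(expr.columns),
        strata=strata,
        sample_ids=list(expr.index),
    )


def write_cohort(cohort: CohortDataset, out_dir, orientation: str = "samples_in_rows") -> dict:
    """Write a cohort as expression/labels(/strata) TSVs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        cohort.expression, index=cohort.sample_ids, columns=cohort.gene_ids
    )
    if orientation == "genes_in_rows":
        frame = frame.T
    expr_path = out_dir / f"{cohort.cohort_id}.expression.tsv"
    frame.to_csv(expr_path, sep="\t", float_format="%.10g")
    labels_path = out_dir / f"{cohort.cohort_id}.labels.tsv"
    pd.Series(cohort.labels, index=cohort.sample_ids, name="label").to_csv(
        labels_path, sep="\t", index_label="sample"
    )
    paths = {"expression": expr_path, "labels": labels_path}
    if cohort.strata is not None:
        strata_path = out_dir / f"{cohort.cohort_id}.strata.tsv"
        pd.Series(cohort.strata, index=cohort.sample_ids, name="stratum").to_csv(
            strata_path, sep="\t", index_label="sample"
        )
        paths["strata"] = strata_path
    return paths


# ---------------------------------------------------------------------------
# classifier serialization (bit-exact round trip)
# ---------------------------------------------------------------------------


def _encode_float(x: float):
    if x == float("-inf"):
        return "-inf"
    return x


def _decode_float(x) -> float:
    if x == "-inf":
        return float("-inf")
    return float(x)


def classifier_to_dict(classifier: MaxLogisticClassifier) -> dict:
    return {
        "format": "maxlogit-classifier-v1",
        "threshold": classifier.threshold,
        "groups": [list(g) for g in classifier.partition.groups],
        "cohorts": {
            cid: [
                {
                    "intercept": _encode_float(f.intercept),
                    "genes": list(f.genes),
                    "coefficients": list(f.coefficients),
                }
                for f in factors
            ]
            for cid, factors in classifier.per_cohort_factors.items()
        },
    }


def classifier_from_dict(doc: dict) -> MaxLogisticClassifier:
    partition = GenePartition(tuple(tuple(g) for g in doc["groups"]))
    cohorts = {
        cid: [
            CompetingFactor(
                intercept=_decode_float(f["intercept"]),
                coefficients=tuple(f["coefficients"]),
                genes=tuple(f["genes"]),
            )
            for f in factors
        ]
        for cid, factors in doc["cohorts"].items()
    }
    return MaxLogisticClassifier(partition, cohorts, threshold=float(doc["threshold"]))


def save_classifier(classifier: MaxLogisticClassifier, path) -> None:
    Path(path).write_text(json.dumps(classifier_to_dict(classifier), indent=1))


def load_classifier(path) -> MaxLogisticClassifier:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "maxlogit-classifier-v1":
        raise ValueError(f"{path} is not a maxlogit classifier document")
    return classifier_from_dict(doc)
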