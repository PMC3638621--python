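"""Reading, writing and validation of binary symptom tables.

The central container is :class:`SymptomDataset`: one row per patient, one
column per symptom, all values binary on input (fractional values in [0, 1]
appear only after pairwise undersampling averages merged samples), plus one
binary syndrome label per patient (1 = syndrome present).

The module also ships, as packaged TSV resources, the published reference
tables for the wind-phlegm collateral obstruction syndrome study: class
counts (``table1``), per-symptom information gains (``table2``), the core
symptom to HPO term mapping (``table3``) and the mined pathway pattern
(``table4``). They serve as replayable ground truth for the fixture tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError

__all__ = [
    "SymptomDataset",
    "read_symptom_table",
    "write_symptom_table",
    "load_fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("table1", "table2", "table3", "table4")


@dataclass(frozen=True)
class SymptomDataset:
    """Patients x binary symptoms with a per-patient syndrome label.

    Attributes
    ----------
    sample_ids:
        Opaque per-patient identifiers, one per row.
    symptom_names:
        Column names, order-preserving.
    matrix:
        float array of shape (n_samples, n_symptoms); values in [0, 1].
        Raw (loaded or simulated) data is strictly 0/1; fractional values
        arise only from sample mergence.
    labels:
        int array in {0, 1}; 1 = syndrome present (the positive, majority
        class in the reference study).
    """

    sample_ids: tuple
    symptom_names: tuple
    matrix: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "symptom_names", tuple(self.symptom_names))
        n, m = matrix.shape
        if len(self.sample_ids) != n or len(labels) != n:
            raise ValidationError(
                f"row mismatch: {n} matrix rows, {len(self.sample_ids)} ids, "
                f"{len(labels)} labels"
            )
        if len(self.symptom_names) != m:
            raise ValidationError(
                f"column mismatch: {m} matrix columns, "
                f"{len(self.symptom_names)} symptom names"
            )
        if len(set(self.symptom_names)) != m:
            dupes = sorted(
                {s for s in self.symptom_names if self.symptom_names.count(s) > 1}
            )
            raise ValidationError(f"duplicate symptom names: {dupes}")
        if matrix.size and (matrix.min() < 0 or matrix.max() > 1):
            raise ValidationError("matrix values must lie in [0, 1]")
        if not np.isin(labels, (0, 1)).all():
            raise ValidationError("labels must be 0/1")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_symptoms(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(self.n_samples - self.labels.sum())

    @property
    def class_ratio(self) -> float:
        """Majority:minority imbalance ratio, positives over negatives."""
        if self.n_negative == 0:
            return float("inf")
        return self.n_positive / self.n_negative

    def restrict(self, symptoms: Sequence[str]) -> "SymptomDataset":
        """Project onto the given symptom columns, in the given order."""
        index = {name: j for j, name in enumerate(self.symptom_names)}
        missing = [s for s in symptoms if s not in index]
        if missing:
            raise ValidationError(f"unknown symptoms: {missing}")
        cols = [index[s] for s in symptoms]
        return replace(
            self, symptom_names=tuple(symptoms), matrix=self.matrix[:, cols]
        )

    def subset(self, rows: Sequence[int]) -> "SymptomDataset":
        rows = list(rows)
        return replace(
            self,
            sample_ids=tuple(self.sample_ids[i] for i in rows),
            matrix=self.matrix[rows],
            labels=self.labels[rows],
        )

    def to_frame(self, label_column: str = "syndrome") -> pd.DataFrame:
        frame = pd.DataFrame(
            self.matrix, columns=list(self.symptom_names), index=list(self.sample_ids)
        )
        frame[label_column] = self.labels
        return frame

    def summary(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_symptoms": self.n_symptoms,
            "n_positive": self.n_positive,
            "n_negative": self.n_negative,
            "class_ratio": round(self.class_ratio, 2),
        }


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_symptom_table(
    path: str | Path, label_column: str = "syndrome", delimiter: str | None = None
) -> SymptomDataset:
    """Read a delimited symptom table into a validated :class:`SymptomDataset`.

    The file must have a header row; every data cell (including labels) must
    parse to 0 or 1. Column order is preserved. The delimiter is inferred
    from the extension (``.csv`` comma, anything else tab) unless given.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    if label_column not in frame.columns:
        raise ConfigError(
            f"label column {label_column!r} not found in {path.name}; "
            f"columns: {list(frame.columns)[:5]}..."
        )
    symptom_cols = [c for c in frame.columns if c != label_column]
    for col in [label_column, *symptom_cols]:
        values = frame[col]
        bad = values[~values.isin((0, 1))]
        if len(bad):
            row = bad.index[0]
            raise ValidationError(
                f"non-binary value {bad.iloc[0]!r} at row {row!r}, column {col!r}"
            )
    return SymptomDataset(
        sample_ids=tuple(str(i) for i in frame.index),
        symptom_names=tuple(symptom_cols),
        matrix=frame[symptom_cols].to_numpy(dtype=float),
        labels=frame[label_column].to_numpy(dtype=int),
    )


def write_symptom_table(
    dataset: SymptomDataset,
    path: str | Path,
    label_column: str = "syndrome",
    delimiter: str | None = None,
) -> Path:
    """Write a dataset so that :func:`read_symptom_table` round-trips it."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    frame = dataset.to_frame(label_column)
    # keep integral values as integers so binary tables round-trip bytewise
    if np.array_equal(dataset.matrix, dataset.matrix.astype(int)):
        frame[list(dataset.symptom_names)] = dataset.matrix.astype(int)
    frame.to_csv(path, sep=sep, index_label="sample_id")
    return path


def _fixture_frame(name: str) -> pd.DataFrame:
    ref = resources.files("zhengkit.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def load_fixture(name: str):
    """Load one of the packaged reference tables.

    ``table1`` -> dict of class counts; ``table2`` -> list of
    (symptom, gain) sorted non-increasing; ``table3`` -> dict
    symptom -> list of (term_id, term_name) (empty list for symptoms absent
    from the ontology); ``table4`` -> list of dicts with keys ``symbol``,
    ``pathways`` (frozenset), ``description``, ``count``.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    if name == "table1":
        row = _fixture_frame("table1").iloc[0]
        return {
            "positive": int(row["positive"]),
            "negative": int(row["negative"]),
            "total": int(row["total"]),
            "features": int(row["features"]),
        }
    if name == "table2":
        frame = _fixture_frame("table2")
        return [
            (str(r.symptom), float(r.information_gain)) for r in frame.itertuples()
        ]
    if name == "table3":
        frame = _fixture_frame("table3")
        mapping: dict[str, list[tuple[str, str]]] = {}
        for r in frame.itertuples():
            terms = mapping.setdefault(str(r.core_symptom), [])
            if isinstance(r.term_id, str) and r.term_id:
                terms.append((r.term_id, str(r.term_name)))
        return mapping
    frame = _fixture_frame("table4")
    return [
        {
            "symbol": str(r["symbol"]),
            "pathways": frozenset(str(r["pathway_entries"]).split(";")),
            "description": str(r["pathway_description"]),
            "count": int(r["count"]),
        }
        for r in frame.to_dict("records")
    ]
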