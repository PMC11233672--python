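"""Core in-memory containers shared across the pipeline.

Expression data is stored gene-by-sample, matching the orientation of the
public cohort exports the tool is designed to ingest (TCGA Firebrowse,
cBioPortal and SCAN-B matrices all ship genes in rows).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "SampleScores",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values on a stated measurement scale.

    Missing measurements are represented by *gene absence*, never by NaN:
    every stored value must be finite.  ``scale_tag`` is a free-text label
    such as ``"logFPKM"`` or ``"median-intensity"`` recording what the
    numbers mean; the pipeline itself is scale-agnostic because it only
    consumes within-sample ranks.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    scale_tag: str = "unknown"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, scale_tag: str = "unknown") -> "ExpressionMatrix":
        return cls(
            gene_ids=list(frame.index),
            sample_ids=list(frame.columns),
            values=frame.to_numpy(dtype=float),
            scale_tag=scale_tag,
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``genes`` (which must all be present)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            gene_ids=list(genes),
            sample_ids=list(self.sample_ids),
            values=self.values[rows, :].copy(),
            scale_tag=self.scale_tag,
        )

    def sample(self, sample_id: str) -> pd.Series:
        """One sample's values as a gene-indexed Series."""
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=sample_id)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the MSigDB Hallmark collection parsed from GMT).

    Duplicate genes within a set are collapsed, preserving first occurrence;
    empty sets are rejected.
    """

    sets: Mapping[str, list]

    def __post_init__(self) -> None:
        cleaned = {}
        for name, genes in self.sets.items():
            deduped = list(dict.fromkeys(genes))
            if not deduped:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = deduped
        self.sets = cleaned

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


@dataclass
class SampleScores:
    """Per-sample coordinates on the retained principal components."""

    sample_ids: list
    coordinates: np.ndarray
    component_labels: list = field(default_factory=list)
    model_id: str = ""

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be a 2-D sample-by-component array")
        if self.coordinates.shape[0] != len(self.sample_ids):
            raise ValueError("row count does not match sample_ids")
        if not self.component_labels:
            self.component_labels = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        if len(self.component_labels) != self.coordinates.shape[1]:
            raise ValueError("component label count does not match coordinates")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite sample coordinates")
        _check_unique(self.sample_ids, "sample")

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.coordinates, index=self.sample_ids, columns=self.component_labels
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, model_id: str = "") -> "SampleScores":
        return cls(
            sample_ids=list(frame.index),
            coordinates=frame.to_numpy(dtype=float),
            component_labels=list(frame.columns),
            model_id=model_id,
        )
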