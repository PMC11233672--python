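"""ASIS — Absolute Scorer for Individual Samples.

A gene-set score that is absolute (comparable across cohorts) and strictly
single-sample.  The model is the same stable-gene rank normalization and
uncentered PCA, but fitted on the *full* shared gene universe rather than
the top-variable panel.  For each sample the batch components (PC1/PC2 by
default) are regressed out of the normalized expression vector and the
score of a gene set is simply the sum of the residual values over the
set's genes.  Because anything in the span of the batch loadings is
annihilated exactly, the scores are free of platform/cohort effects by
construction, and the stable-gene set scores near 0 on data resembling the
training distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSetCollection
from .embedding import EmbeddingModel, fit_embedding
from .normalization import GeneSelection, normalize_sample, rank_normalize

__all__ = [
    "ASISModel",
    "ASISScore",
    "asis_fit",
    "asis_regress",
    "asis_score",
    "score_cohort",
]


@dataclass
class ASISModel:
    """Full-universe embedding plus the components treated as batch."""

    embedding: EmbeddingModel
    batch_components: tuple = (1, 2)  # 1-based component numbers

    def __post_init__(self) -> None:
        self.batch_components = tuple(int(c) for c in self.batch_components)
        if not self.batch_components:
            raise ValueError("need at least one batch component")
        for c in self.batch_components:
            if not 1 <= c <= self.embedding.n_components:
                raise ValueError(
                    f"batch component {c} outside retained components "
                    f"1..{self.embedding.n_components}"
                )

    @property
    def universe_genes(self) -> list:
        return self.embedding.feature_genes

    @property
    def stable_genes(self) -> list:
        return self.embedding.stable_genes

    def selection(self) -> GeneSelection:
        stable = set(self.stable_genes)
        return GeneSelection(
            variable_genes=[g for g in self.universe_genes if g not in stable],
            stable_genes=self.stable_genes,
        )

    def batch_loadings(self) -> np.ndarray:
        cols = [c - 1 for c in self.batch_components]
        return self.embedding.loadings[:, cols]


@dataclass
class ASISScore:
    sample_id: str
    set_name: str
    score: float
    coverage: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0, 1]")
        if not np.isfinite(self.score):
            raise ValueError("score must be finite")


def asis_fit(
    cohort_matrices: Sequence[ExpressionMatrix],
    stable_genes: Sequence[str],
    expression_filter: Callable[[pd.DataFrame], pd.Series] | None = None,
    min_mean: float = 0.0,
    n_components: int = 4,
    n_train: int | None = None,
    er_anchor_gene: str | None = None,
    seed: int | None = None,
    cohort_names: Sequence[str] | None = None,
) -> ASISModel:
    """Fit the full-universe model used for absolute scoring.

    The gene universe is every gene shared by all cohorts that passes the
    expression filter (default: mean expression above ``min_mean`` in every
    cohort).  Rank normalization over the whole universe uses the same
    stable-gene divisor, then an uncentered PCA with ``n_components >= 2``
    is fitted on ``n_train`` pooled random training samples.
    """
    if n_components < 2:
        raise ValueError("ASIS needs at least 2 retained components")
    stable_genes = list(stable_genes)
    if cohort_names is None:
        cohort_names = [f"cohort{i + 1}" for i in range(len(cohort_matrices))]

    shared = set.intersection(*(set(m.gene_ids) for m in cohort_matrices))
    means = pd.DataFrame(
        {
            name: m.to_frame().mean(axis=1).reindex(sorted(shared))
            for name, m in zip(cohort_names, cohort_matrices)
        }
    )
    if expression_filter is not None:
        mask = expression_filter(means)
    else:
        mask = (means > min_mean).all(axis=1)
    universe = sorted(means.index[mask])
    dropped_stable = [g for g in stable_genes if g not in universe]
    if dropped_stable:
        raise ValueError(
            f"expression filter removed stable genes: {dropped_stable[:5]}"
        )
    if not universe:
        raise ValueError("expression filter left an empty gene universe")

    selection = GeneSelection(
        variable_genes=[g for g in universe if g not in set(stable_genes)],
        stable_genes=stable_genes,
    )
    pooled = pd.concat(
        [m.to_frame().reindex(selection.feature_genes) for m in cohort_matrices], axis=1
    )
    cohort_of = {
        s: name
        for name, m in zip(cohort_names, cohort_matrices)
        for s in m.sample_ids
    }
    matrix = ExpressionMatrix.from_frame(pooled)
    normalized = rank_normalize(matrix, selection)

    sample_ids = list(normalized.sample_ids)
    if n_train is not None and n_train < len(sample_ids):
        rng = np.random.default_rng(seed)
        train_idx = np.sort(rng.choice(len(sample_ids), size=n_train, replace=False))
    else:
        train_idx = np.arange(len(sample_ids))
    train = type(normalized)(
        gene_ids=normalized.gene_ids,
        sample_ids=[sample_ids[i] for i in train_idx],
        values=normalized.values[:, train_idx],
        stable_genes=normalized.stable_genes,
    )
    counts = pd.Series([cohort_of[s] for s in train.sample_ids]).value_counts()
    model, _ = fit_embedding(
        train,
        n_components=n_components,
        er_anchor_gene=er_anchor_gene,
        seed=seed,
        training_info={"cohort_counts": counts.to_dict(), "kind": "asis"},
    )
    return ASISModel(embedding=model)


def asis_regress(model: ASISModel, sample: pd.Series | np.ndarray) -> pd.Series:
    """Remove the batch components from one normalized sample vector.

    Least-squares regression (no intercept — the batch span already
    contains the mean direction) of the sample on the batch loading
    vectors; returns sample − fitted, which is orthogonal to every batch
    loading.  Genes missing from the sample enter as 0, exactly as in
    projection.
    """
    genes = model.universe_genes
    if isinstance(sample, pd.Series):
        v = sample.reindex(genes).fillna(0.0).to_numpy(dtype=float)
    else:
        v = np.asarray(sample, dtype=float)
        if v.shape != (len(genes),):
            raise ValueError("vector length does not match the gene universe")
    B = model.batch_loadings()
    # orthonormal columns: least-squares coefficients are just B^T v
    residual = v - B @ (B.T @ v)
    return pd.Series(residual, index=genes)


def asis_score(
    residual: pd.Series,
    gene_set: Sequence[str],
    set_name: str = "",
    sample_id: str = "",
    min_coverage: float = 0.75,
) -> ASISScore:
    """Sum the batch-free residual expression over a gene set.

    ``coverage`` is the fraction of the (de-duplicated) set found in the
    universe; scores with coverage below ``min_coverage`` are still
    computed but flagged (coverage >= min_coverage passes).
    """
    genes = list(dict.fromkeys(gene_set))
    if not genes:
        raise ValueError("gene set is empty")
    present = [g for g in genes if g in residual.index]
    if not present:
        raise ValueError(f"gene set {set_name!r} shares no genes with the universe")
    coverage = len(present) / len(genes)
    score = float(residual.loc[present].sum())
    return ASISScore(
        sample_id=sample_id,
        set_name=set_name,
        score=score,
        coverage=coverage,
        flagged=coverage < min_coverage,
    )


def score_cohort(
    model: ASISModel,
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    min_coverage: float = 0.75,
) -> pd.DataFrame:
    """Score every sample of a cohort against every gene set.

    Each sample goes through the identical single-sample path
    (normalize → regress → sum), so scoring a cohort and scoring one
    held-out sample alone give bitwise-identical numbers.
    """
    selection = model.selection()
    frame = matrix.to_frame()
    rows = []
    for sample_id in matrix.sample_ids:
        normalized = normalize_sample(frame[sample_id], selection)
        residual = asis_regress(model, normalized)
        for set_name, genes in collection.items():
            sc = asis_score(
                residual, genes, set_name=set_name, sample_id=sample_id,
                min_coverage=min_coverage,
            )
            rows.append(
                {
                    "sample_id": sc.sample_id,
                    "set_name": sc.set_name,
                    "score": sc.score,
                    "coverage": sc.coverage,
                    "flag": sc.flagged,
                }
            )
    return pd.DataFrame.from_records(rows)
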