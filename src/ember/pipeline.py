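"""Glue that chains selection -> normalization -> embedding for whole studies."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleScores
from .embedding import EmbeddingModel, fit_embedding, project, transform
from .normalization import (
    GeneSelection,
    NormalizedMatrix,
    normalize_sample,
    rank_normalize,
    select_feature_genes,
)

__all__ = ["pool_cohorts", "train_embedding", "embed_samples"]


def pool_cohorts(
    cohort_matrices: Sequence[ExpressionMatrix],
    selection: GeneSelection,
) -> NormalizedMatrix:
    """Rank-normalize every cohort on the feature panel and pool the samples."""
    pooled = pd.concat(
        [m.to_frame().reindex(selection.feature_genes) for m in cohort_matrices],
        axis=1,
    )
    return rank_normalize(ExpressionMatrix.from_frame(pooled), selection)


def train_embedding(
    cohort_matrices: Sequence[ExpressionMatrix],
    stable_genes: Sequence[str],
    n_variable: int = 1000,
    n_train: int = 1000,
    n_components: int = 4,
    er_anchor_gene: str | None = None,
    seed: int | None = None,
    cohort_names: Sequence[str] | None = None,
):
    """Full training pass on one or more cohorts.

    Selects the top-CV variable genes plus the stable panel, rank-normalizes
    the pooled samples, fits the uncentered PCA on ``n_train`` random pooled
    training samples (fixed seed) and embeds *all* samples with the fitted
    loadings.

    Returns ``(selection, normalized, model, scores, train_ids)``.
    """
    if cohort_names is None:
        cohort_names = [m.scale_tag for m in cohort_matrices]
    selection = select_feature_genes(
        cohort_matrices, stable_genes, n_variable=n_variable, cohort_names=cohort_names
    )
    normalized = pool_cohorts(cohort_matrices, selection)
    ids = list(normalized.sample_ids)
    rng = np.random.default_rng(seed)
    if n_train < len(ids):
        tr = np.sort(rng.choice(len(ids), size=n_train, replace=False))
    else:
        tr = np.arange(len(ids))
    train = NormalizedMatrix(
        gene_ids=normalized.gene_ids,
        sample_ids=[ids[i] for i in tr],
        values=normalized.values[:, tr],
        stable_genes=normalized.stable_genes,
    )
    cohort_of = {
        s: name for name, m in zip(cohort_names, cohort_matrices) for s in m.sample_ids
    }
    counts = pd.Series([cohort_of[s] for s in train.sample_ids]).value_counts()
    model, _ = fit_embedding(
        train,
        n_components=n_components,
        er_anchor_gene=er_anchor_gene,
        seed=seed,
        training_info={"cohort_counts": counts.to_dict()},
    )
    scores = transform(model, normalized)
    return selection, normalized, model, scores, [ids[i] for i in tr]


def embed_samples(model: EmbeddingModel, matrix: ExpressionMatrix) -> SampleScores:
    """Normalize and project arbitrary samples, tolerating missing genes.

    When the matrix carries the full feature panel this is the vectorized
    normalize-then-project path; otherwise each sample is re-ranked among
    its available genes and missing genes contribute 0.
    """
    selection = GeneSelection(
        variable_genes=[g for g in model.feature_genes
                        if g not in set(model.stable_genes)],
        stable_genes=model.stable_genes,
    )
    present = set(matrix.gene_ids)
    if all(g in present for g in model.feature_genes):
        normalized = rank_normalize(matrix, selection)
        return transform(model, normalized)
    frame = matrix.to_frame()
    coords = np.empty((matrix.n_samples, model.n_components))
    for j, sid in enumerate(matrix.sample_ids):
        normalized = normalize_sample(frame[sid], selection)
        coords[j] = project(model, normalized)
    return SampleScores(
        sample_ids=list(matrix.sample_ids),
        coordinates=coords,
        component_labels=list(model.component_labels),
    )
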