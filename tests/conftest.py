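"""Shared fixtures: tiny hand-built matrices and cached synthetic studies."""

import numpy as np
import pandas as pd
import pytest

from ember import (
    ExpressionMatrix,
    ProgramSpec,
    SimulationConfig,
    asis_fit,
    simulate,
    train_embedding,
)


def scaled_programs(factor: float) -> dict:
    """Default program structure with gene counts scaled for small fixtures."""
    base = SimulationConfig().programs
    return {
        name: ProgramSpec(
            n_genes=max(6, int(spec.n_genes * factor)),
            effect=spec.effect,
            subtype_means=spec.subtype_means,
            within_subtype_sd=spec.within_subtype_sd,
        )
        for name, spec in base.items()
    }


@pytest.fixture
def tiny_matrix():
    """5 genes x 4 samples with easy hand-checkable values."""
    values = np.array(
        [
            [10.0, 1.0, 4.0, 8.0],
            [2.0, 2.0, 3.0, 1.0],
            [7.0, 8.0, 9.0, 6.0],
            [1.0, 4.0, 2.0, 3.0],
            [5.0, 6.0, 7.0, 4.0],
        ]
    )
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3", "g4", "g5"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=values,
        scale_tag="toy",
    )


def _small_config(seed=123):
    """Desk-scale study: 2 cohorts x 140 samples, 500 genes, 20 stable.

    Programs are scaled to a quarter of their default gene counts so the
    program/background ratio matches the default study conditions.
    """
    return SimulationConfig(
        n_samples_per_cohort=140,
        n_genes=500,
        n_stable_genes=20,
        programs=scaled_programs(0.25),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_study():
    return simulate(_small_config())


@pytest.fixture(scope="session")
def small_pipeline(small_study):
    """Trained small embedding: (study, selection, normalized, model, scores, train_ids)."""
    selection, normalized, model, scores, train_ids = train_embedding(
        small_study.cohorts,
        small_study.stable_gene_ids,
        n_variable=200,
        n_train=200,
        er_anchor_gene=small_study.er_hub_gene,
        seed=7,
    )
    return small_study, selection, normalized, model, scores, train_ids


@pytest.fixture(scope="session")
def default_study():
    """The generator at its default settings (the documented study conditions)."""
    return simulate(SimulationConfig())


@pytest.fixture(scope="session")
def default_pipeline(default_study):
    selection, normalized, model, scores, train_ids = train_embedding(
        default_study.cohorts,
        default_study.stable_gene_ids,
        n_variable=1000,
        n_train=1000,
        er_anchor_gene=default_study.er_hub_gene,
        seed=11,
    )
    return default_study, selection, normalized, model, scores, train_ids


@pytest.fixture(scope="session")
def small_asis(small_study):
    model = asis_fit(
        small_study.cohorts,
        small_study.stable_gene_ids,
        n_train=200,
        er_anchor_gene=small_study.er_hub_gene,
        seed=7,
    )
    pooled = ExpressionMatrix.from_frame(
        pd.concat([m.to_frame() for m in small_study.cohorts], axis=1)
    )
    return small_study, model, pooled
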