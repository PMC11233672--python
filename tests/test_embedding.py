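"""Uncentered PCA fit, projection, sign anchoring and the scaled-PCA comparison."""

import numpy as np
import pandas as pd
import pytest

from ember import (
    NormalizedMatrix,
    align_signs,
    fit_embedding,
    project,
    scaled_pca_equivalence,
    transform,
)


def _normalized(values, stable=None):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(
        gene_ids=genes,
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        stable_genes=stable or [],
    )


def _random_normalized(seed=0, p=30, n=20):
    rng = np.random.default_rng(seed)
    return _normalized(rng.uniform(0.1, 2.0, size=(p, n)))


class TestFit:
    def test_rank_one_matrix_exact(self):
        v = np.array([1.0, 2.0, 3.0])
        weights = np.array([1.0, 0.5, 2.0, 1.5])
        norm = _normalized(np.outer(v, weights))
        model, scores = fit_embedding(norm, n_components=1)
        # scores proportional to sample norms; rank-1 reconstruction is exact
        norms = np.linalg.norm(norm.values, axis=0)
        assert np.allclose(np.abs(scores.coordinates[:, 0]), norms)
        recon = model.loadings @ scores.coordinates.T
        assert np.allclose(recon, norm.values, atol=1e-10)

    def test_training_scores_equal_projection(self):
        norm = _random_normalized(1)
        model, scores = fit_embedding(norm, n_components=4)
        reproj = transform(model, norm)
        assert np.allclose(scores.coordinates, reproj.coordinates, atol=1e-10)

    def test_orthonormal_loadings(self):
        model, _ = fit_embedding(_random_normalized(2), n_components=4)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_variance_nonincreasing(self):
        model, _ = fit_embedding(_random_normalized(3), n_components=4)
        ev = model.training_info["explained_variance"]
        assert all(a >= b for a, b in zip(ev, ev[1:]))

    def test_agrees_with_independent_uncentered_svd(self):
        """Cross-check against sklearn's TruncatedSVD (uncentered by design)."""
        from sklearn.decomposition import TruncatedSVD

        norm = _random_normalized(4, p=40, n=25)
        model, scores = fit_embedding(norm, n_components=3)
        ref = TruncatedSVD(n_components=3, algorithm="arpack").fit_transform(
            norm.values.T
        )
        for k in range(3):
            r = np.corrcoef(scores.coordinates[:, k], ref[:, k])[0, 1]
            assert abs(r) > 1 - 1e-8

    def test_rank_deficient_rejected(self):
        norm = _normalized(np.outer([1.0, 2.0, 3.0], [1.0, 1.5, 2.0, 2.5]))
        with pytest.raises(ValueError, match="rank"):
            fit_embedding(norm, n_components=2)

    def test_pc1_tracks_gene_means(self, default_pipeline):
        """PC1 of the uncentered fit acts as centering: its loadings follow the gene means."""
        study, selection, normalized, model, scores, train_ids = default_pipeline
        train_set = set(train_ids)
        cols = [i for i, s in enumerate(normalized.sample_ids) if s in train_set]
        gene_means = normalized.values[:, cols].mean(axis=1)
        r = np.corrcoef(model.loadings[:, 0], gene_means)[0, 1]
        assert round(r, 2) == 1.0


class TestProject:
    def test_idempotent_on_training_sample(self):
        norm = _random_normalized(5)
        model, scores = fit_embedding(norm, n_components=4)
        sample = pd.Series(norm.values[:, 3], index=norm.gene_ids)
        assert np.allclose(project(model, sample), scores.coordinates[3], atol=1e-10)

    def test_linearity(self):
        norm = _random_normalized(6)
        model, _ = fit_embedding(norm, n_components=4)
        x = pd.Series(norm.values[:, 0], index=norm.gene_ids)
        y = pd.Series(norm.values[:, 1], index=norm.gene_ids)
        lhs = project(model, 2.0 * x + 3.0 * y)
        rhs = 2.0 * project(model, x) + 3.0 * project(model, y)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_single_gene_sample_is_scaled_loading_row(self):
        norm = _random_normalized(7)
        model, _ = fit_embedding(norm, n_components=4)
        coords, info = project(model, {"g5": 2.5}, return_info=True)
        i = model.feature_genes.index("g5")
        assert np.allclose(coords, 2.5 * model.loadings[i])
        assert info["high_missingness"]

    def test_no_shared_genes_rejected(self):
        model, _ = fit_embedding(_random_normalized(8), n_components=4)
        with pytest.raises(ValueError, match="no genes"):
            project(model, {"absent": 1.0})

    def test_zero_fill_of_nothing_equals_full(self):
        norm = _random_normalized(9)
        model, scores = fit_embedding(norm, n_components=4)
        sample = pd.Series(norm.values[:, 2], index=norm.gene_ids)
        full = project(model, sample)
        trimmed = project(model, sample[sample.index])  # same support
        assert np.array_equal(full, trimmed)


class TestAlignSigns:
    def test_idempotent(self):
        model, scores = fit_embedding(_random_normalized(10), n_components=4)
        rules = {"PC3": ("g4", 1), "PC4": ("g7", -1)}
        once, s_once = align_signs(model, rules, scores)
        twice, s_twice = align_signs(once, rules, s_once)
        assert np.array_equal(once.loadings, twice.loadings)
        assert np.array_equal(s_once.coordinates, s_twice.coordinates)

    def test_anchor_sign_enforced(self):
        model, _ = fit_embedding(_random_normalized(11), n_components=4)
        aligned = align_signs(model, {"PC2": ("g3", -1)})
        assert aligned.loadings[aligned.feature_genes.index("g3"), 1] < 0

    def test_reflected_fit_reanchors_to_same_geometry(self):
        """A fit reflected along any subset of axes is restored by re-anchoring."""
        from ember import EmbeddingModel
        from ember.datatypes import SampleScores

        norm = _random_normalized(12)
        model, scores = fit_embedding(norm, n_components=3)
        flips = np.array([1.0, -1.0, -1.0])
        reflected = EmbeddingModel(
            feature_genes=model.feature_genes,
            stable_genes=model.stable_genes,
            loadings=model.loadings * flips,
            component_labels=list(model.component_labels),
            sign_anchor=list(model.sign_anchor),
            training_info=dict(model.training_info),
        )
        ref_scores = SampleScores(
            sample_ids=scores.sample_ids,
            coordinates=scores.coordinates * flips,
            component_labels=list(scores.component_labels),
        )
        rules = {lbl: a for lbl, a in zip(model.component_labels, model.sign_anchor)}
        restored, restored_scores = align_signs(reflected, rules, ref_scores)
        assert np.array_equal(restored.loadings, model.loadings)
        assert np.array_equal(restored_scores.coordinates, scores.coordinates)

    def test_refit_on_resample_correlates_positively(self, small_pipeline):
        """After anchoring, PC3 keeps its orientation across retrainings."""
        study, selection, normalized, model, scores, _ = small_pipeline
        rng = np.random.default_rng(99)
        ids = list(normalized.sample_ids)
        tr = np.sort(rng.choice(len(ids), size=180, replace=False))
        sub = NormalizedMatrix(
            gene_ids=normalized.gene_ids,
            sample_ids=[ids[i] for i in tr],
            values=normalized.values[:, tr],
            stable_genes=normalized.stable_genes,
        )
        refit, _ = fit_embedding(sub, n_components=4, er_anchor_gene=study.er_hub_gene)
        rules = {lbl: a for lbl, a in zip(model.component_labels, model.sign_anchor)}
        refit = align_signs(refit, rules)
        new_scores = transform(refit, normalized)
        r = np.corrcoef(scores.coordinates[:, 2], new_scores.coordinates[:, 2])[0, 1]
        assert r > 0.5


class TestScaledEquivalence:
    def test_exact_low_rank_construction(self):
        """Exact rank-2 batch (mean+offset) plus rank-2 biology: correlations 1.

        Gene directions are orthonormal Hadamard columns (equal per-gene
        variance, so scaling is a uniform rescale) and sample profiles are
        exactly orthogonal with well-separated amplitudes, making the
        component correspondence exact to machine precision.
        """
        from scipy.linalg import hadamard

        rng = np.random.default_rng(13)
        p, n = 64, 48
        U = hadamard(p).astype(float) / np.sqrt(p)  # orthonormal, |entries| equal
        ones = np.ones(n)
        # orthogonalize random profiles against the constant and each other
        raw = rng.standard_normal((n, 3))
        Q, _ = np.linalg.qr(np.column_stack([ones / np.sqrt(n), raw]))
        f_batch = 6.0 * np.sqrt(n) * Q[:, 1]   # per-cohort-like offset profile
        f_bio1 = 3.0 * np.sqrt(n) * Q[:, 2]
        f_bio2 = 1.5 * np.sqrt(n) * Q[:, 3]
        f_mean = 80.0 * ones                    # dominant uncentered direction
        X = (
            np.outer(U[:, 0], f_mean)
            + np.outer(U[:, 1], f_batch)
            + np.outer(U[:, 2], f_bio1)
            + np.outer(U[:, 3], f_bio2)
        )
        assert X.min() > 0
        norm = _normalized(X)
        model, _ = fit_embedding(norm, n_components=4)
        rep = scaled_pca_equivalence(norm, model)
        assert rep["corr_pc3_scaled_pc2"] > 1 - 1e-10
        assert rep["corr_pc4_scaled_pc3"] > 1 - 1e-10

    def test_default_cohorts_round_to_one(self, default_pipeline):
        study, selection, normalized, model, *_ = default_pipeline
        rep = scaled_pca_equivalence(normalized, model)
        assert round(rep["corr_pc3_scaled_pc2"], 1) == 1.0
        assert round(rep["corr_pc4_scaled_pc3"], 1) == 1.0
        # |PC2 loadings| follow the post-centering gene standard deviations
        assert rep["corr_abs_pc2_loading_vs_sd"] > 0.5
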