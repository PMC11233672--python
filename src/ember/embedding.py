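"""Uncentered, unscaled PCA embedding and single-sample projection.

The embedding is a plain SVD of the rank-normalized training matrix with no
centering and no scaling.  Because every normalized sample carries the same
multiset of rank values up to the stable-gene divisor, the first component
aligns with the per-gene mean (it "centers" the data) and the second
captures the per-sample divisor scale, so platform/batch structure is
absorbed by PC1/PC2 while tumor biology lands on PC3/PC4.

New samples never re-enter the fit: a single sample is embedded by
multiplying the loading matrix with its normalized expression vector, with
genes missing from the sample contributing 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

from .datatypes import SampleScores
from .normalization import NormalizedMatrix

__all__ = [
    "EmbeddingModel",
    "fit_embedding",
    "align_signs",
    "project",
    "transform",
    "scaled_pca_equivalence",
]

_ORTHO_TOL = 1e-8


@dataclass
class EmbeddingModel:
    """Fitted uncentered PCA: ordered feature genes, loadings, sign anchors."""

    feature_genes: list
    stable_genes: list
    loadings: np.ndarray  # genes x components, orthonormal columns
    component_labels: list = field(default_factory=list)
    sign_anchor: list = field(default_factory=list)  # (gene, sign) per component
    training_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_genes = list(self.feature_genes)
        self.stable_genes = list(self.stable_genes)
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.shape[0] != len(self.feature_genes):
            raise ValueError("loading rows do not match feature genes")
        if not self.component_labels:
            self.component_labels = [f"PC{i + 1}" for i in range(self.loadings.shape[1])]
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-6):
            raise ValueError("loading columns must be orthonormal")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def loadings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.loadings, index=self.feature_genes, columns=self.component_labels
        )

    def gene_index(self) -> dict:
        return {g: i for i, g in enumerate(self.feature_genes)}


def fit_embedding(
    normalized: NormalizedMatrix,
    n_components: int = 4,
    er_anchor_gene: str | None = None,
    seed: int | None = None,
    training_info: dict | None = None,
) -> tuple[EmbeddingModel, SampleScores]:
    """SVD of the uncentered, unscaled normalized matrix.

    Loadings are the right singular vectors over genes; training scores are
    the data projected onto them.  Component signs are resolved
    deterministically: PC1 positive along the per-gene mean direction, PC3
    positive on ``er_anchor_gene`` if given (an ER-program hub such as ESR1
    in real use), every other component positive on its largest-|loading|
    gene.
    """
    X = normalized.values.T  # samples x genes
    n, p = X.shape
    if n < n_components:
        raise ValueError(f"need at least {n_components} samples, got {n}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[n_components - 1] <= max(n, p) * np.finfo(float).eps * s[0]:
        raise ValueError(f"matrix rank below {n_components} components")
    loadings = Vt[:n_components].T
    scores = U[:, :n_components] * s[:n_components]

    info = dict(training_info or {})
    info.setdefault("n_training_samples", n)
    info["singular_values"] = [float(v) for v in s[:n_components]]
    info["explained_variance"] = [float(v**2 / n) for v in s[:n_components]]
    if seed is not None:
        info.setdefault("seed", seed)

    model = EmbeddingModel(
        feature_genes=normalized.gene_ids,
        stable_genes=normalized.stable_genes,
        loadings=loadings,
        training_info=info,
    )
    model, scores = _anchor_default(
        model, scores, gene_means=X.mean(axis=0), er_anchor_gene=er_anchor_gene
    )
    sample_scores = SampleScores(
        sample_ids=normalized.sample_ids,
        coordinates=scores,
        component_labels=model.component_labels,
    )
    return model, sample_scores


def _anchor_default(model, scores, gene_means, er_anchor_gene):
    """Resolve reflection indeterminacy of each component."""
    loadings = model.loadings.copy()
    scores = scores.copy()
    anchors = []
    gene_of = model.feature_genes
    for k in range(model.n_components):
        col = loadings[:, k]
        if k == 0:
            # align with the mean direction (PC1 ~ centering)
            sign = 1.0 if float(col @ gene_means) >= 0 else -1.0
        elif k == 2 and er_anchor_gene is not None and er_anchor_gene in gene_of:
            i = gene_of.index(er_anchor_gene)
            if col[i] != 0.0:
                sign = 1.0 if col[i] > 0 else -1.0
                loadings[:, k] = sign * col
                scores[:, k] = sign * scores[:, k]
                anchors.append((er_anchor_gene, 1))
                continue
            # anchor loading exactly 0: fall back to the largest loading
            model.training_info.setdefault("anchor_fallback", []).append(
                model.component_labels[k]
            )
            sign = 1.0 if col[int(np.argmax(np.abs(col)))] > 0 else -1.0
        else:
            sign = 1.0 if col[int(np.argmax(np.abs(col)))] > 0 else -1.0
        loadings[:, k] = sign * col
        scores[:, k] = sign * scores[:, k]
        i_anchor = int(np.argmax(np.abs(loadings[:, k])))
        anchors.append((gene_of[i_anchor], 1 if loadings[i_anchor, k] > 0 else -1))
    model.loadings = loadings
    model.sign_anchor = anchors
    return model, scores


def align_signs(
    model: EmbeddingModel,
    anchor_rules: Mapping[str, tuple[str, int]],
    scores: SampleScores | None = None,
):
    """Flip loading columns so each anchored gene's loading has the desired sign.

    ``anchor_rules`` maps a component label to ``(gene, desired_sign)``.
    Scores, when given, are transformed consistently.  Applying the same
    rules twice is a fixed point.  If an anchor gene's loading is exactly
    zero the component falls back to its largest-|loading| gene, recorded
    in ``training_info['anchor_fallback']``.
    """
    loadings = model.loadings.copy()
    anchors = list(model.sign_anchor)
    coords = scores.coordinates.copy() if scores is not None else None
    idx = model.gene_index()
    for label, (gene, desired) in anchor_rules.items():
        if label not in model.component_labels:
            raise KeyError(f"unknown component {label!r}")
        k = model.component_labels.index(label)
        if gene not in idx:
            raise KeyError(f"anchor gene {gene!r} not in feature set")
        val = loadings[idx[gene], k]
        if val == 0.0:
            j = int(np.argmax(np.abs(loadings[:, k])))
            gene, val = model.feature_genes[j], loadings[j, k]
            model.training_info.setdefault("anchor_fallback", []).append(label)
        if np.sign(val) != np.sign(desired):
            loadings[:, k] = -loadings[:, k]
            if coords is not None:
                coords[:, k] = -coords[:, k]
        if k < len(anchors):
            anchors[k] = (gene, int(np.sign(desired)))
    new_model = EmbeddingModel(
        feature_genes=model.feature_genes,
        stable_genes=model.stable_genes,
        loadings=loadings,
        component_labels=list(model.component_labels),
        sign_anchor=anchors,
        training_info=dict(model.training_info),
    )
    if scores is not None:
        return new_model, SampleScores(
            sample_ids=scores.sample_ids,
            coordinates=coords,
            component_labels=list(scores.component_labels),
            model_id=scores.model_id,
        )
    return new_model


def project(
    model: EmbeddingModel,
    sample: Mapping[str, float] | pd.Series,
    return_info: bool = False,
):
    """Embed one normalized sample: coordinates = loadingsᵀ · sample vector.

    Feature genes absent from the sample contribute 0.  A sample sharing no
    genes with the model is rejected; more than 50% missing genes is
    allowed but flagged in the info dict.
    """
    if isinstance(sample, pd.Series):
        items = sample.items()
    else:
        items = sample.items()
    idx = model.gene_index()
    v = np.zeros(len(model.feature_genes))
    n_hit = 0
    for g, val in items:
        i = idx.get(g)
        if i is not None:
            v[i] = float(val)
            n_hit += 1
    if n_hit == 0:
        raise ValueError("sample shares no genes with the model feature set")
    coords = model.loadings.T @ v
    if return_info:
        frac_missing = 1.0 - n_hit / len(model.feature_genes)
        info = {
            "n_genes_used": n_hit,
            "fraction_missing": frac_missing,
            "high_missingness": frac_missing > 0.5,
        }
        return coords, info
    return coords


def transform(model: EmbeddingModel, normalized: NormalizedMatrix) -> SampleScores:
    """Project every sample of a normalized matrix (full feature panel)."""
    if list(normalized.gene_ids) != list(model.feature_genes):
        frame = normalized.to_frame()
        missing = [g for g in model.feature_genes if g not in frame.index]
        if missing:
            raise KeyError(f"normalized matrix lacks feature genes: {missing[:5]}")
        values = frame.reindex(model.feature_genes).to_numpy()
    else:
        values = normalized.values
    coords = values.T @ model.loadings
    return SampleScores(
        sample_ids=normalized.sample_ids,
        coordinates=coords,
        component_labels=list(model.component_labels),
    )


def scaled_pca_equivalence(
    normalized: NormalizedMatrix,
    model: EmbeddingModel,
    n_components: int = 4,
) -> dict:
    """Compare the uncentered embedding with a centered-and-scaled PCA.

    Fits an ordinary centered, unit-variance PCA on the same normalized
    data and reports, over samples, |corr(uncentered PC3, scaled PC2)| and
    |corr(uncentered PC4, scaled PC3)| (absolute values — the component
    signs are arbitrary).  When PC1/PC2 of the uncentered fit act as
    centering and scaling, both correlations are 1.  Also reports the
    correlation between |PC2 loadings| and the post-centering per-gene
    standard deviation.
    """
    if model.n_components < 4 or n_components < 4:
        raise ValueError("needs at least 4 components in both decompositions")
    X = normalized.values.T
    ember_scores = transform(model, normalized).coordinates

    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    n_dropped = int((~keep).sum())
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    Z = Xc / sds[keep]
    scaled_scores = PCA(n_components=n_components, svd_solver="full").fit_transform(Z)

    r_pc3 = abs(pearsonr(ember_scores[:, 2], scaled_scores[:, 1])[0])
    r_pc4 = abs(pearsonr(ember_scores[:, 3], scaled_scores[:, 2])[0])
    # degenerate when every gene has the same sd (nothing to explain)
    if np.ptp(sds[keep]) < 1e-12 * max(sds.max(), 1.0):
        r_pc2_sd = np.nan
    else:
        r_pc2_sd = pearsonr(np.abs(model.loadings[keep, 1]), sds[keep])[0]
    return {
        "corr_pc3_scaled_pc2": float(r_pc3),
        "corr_pc4_scaled_pc3": float(r_pc4),
        "corr_abs_pc2_loading_vs_sd": float(r_pc2_sd),
        "n_zero_variance_dropped": n_dropped,
    }
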