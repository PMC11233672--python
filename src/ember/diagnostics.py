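"""Evaluation machinery for the embedding.

- LISI (Localized Inverse Simpson Index): perplexity-tuned expected number
  of label categories around each sample; 1 = fully separated labels,
  #categories = fully mixed.  Cohort labels should read near 1 on PC1/PC2
  (the batch components separate platforms) and near #cohorts on PC3/PC4
  (biology mixes them).
- Jaccard retraining stability: refit on random training subsets and ask
  how much each probe sample's k-nearest-neighbor set moves.
- Hexagonal score maps: per-hex mean pathway score over (PC3, PC4).
- Missing-gene sensitivity: displacement of projections as the top-loading
  genes are removed and zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .datatypes import ExpressionMatrix, SampleScores
from .embedding import EmbeddingModel, align_signs, fit_embedding, project, transform
from .normalization import (
    GeneSelection,
    NormalizedMatrix,
    normalize_sample,
    rank_normalize,
    select_feature_genes,
)

__all__ = [
    "LISIResult",
    "StabilityReport",
    "HexGrid",
    "lisi",
    "gene_count_sweep",
    "jaccard_stability",
    "knn_jaccard",
    "hexbin_scores",
    "missing_gene_sensitivity",
]


@dataclass
class LISIResult:
    per_sample_lisi: pd.Series
    label_name: str
    perplexity: float
    n_categories: int

    @property
    def median(self) -> float:
        return float(self.per_sample_lisi.median())

    @property
    def mean(self) -> float:
        return float(self.per_sample_lisi.mean())


@dataclass
class StabilityReport:
    per_probe_jaccard: pd.Series
    k_neighbors: int
    n_seeds: int

    @property
    def mean(self) -> float:
        return float(self.per_probe_jaccard.mean())

    @property
    def sd(self) -> float:
        return float(self.per_probe_jaccard.std(ddof=1))


@dataclass
class HexGrid:
    hex_size: float
    cells: pd.DataFrame  # index: hex id, columns: x, y, count, mean_value
    assignments: pd.Series  # sample -> hex id
    gradient: np.ndarray | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _tune_kernel(dists: np.ndarray, perplexity: float, tol: float = 1e-5,
                 max_iter: int = 64) -> np.ndarray:
    """Gaussian weights over one sample's neighbor distances tuned by
    bisection so the weight entropy matches log(perplexity) (t-SNE style)."""
    target = np.log(perplexity)
    beta, beta_lo, beta_hi = 1.0, 0.0, np.inf
    d2 = dists**2
    d2 = d2 - d2.min()
    for _ in range(max_iter):
        w = np.exp(-beta * d2)
        sw = w.sum()
        if sw == 0:
            w = np.ones_like(d2)
            sw = w.sum()
        p = w / sw
        h = -(p[p > 0] * np.log(p[p > 0])).sum()
        if abs(h - target) < tol:
            break
        if h > target:  # too flat -> sharpen
            beta_lo = beta
            beta = beta * 2 if np.isinf(beta_hi) else (beta + beta_hi) / 2
        else:
            beta_hi = beta
            beta = beta / 2 if beta_lo == 0 else (beta + beta_lo) / 2
    return w / w.sum()


def lisi(
    coords: pd.DataFrame | np.ndarray,
    labels: pd.Series | Sequence,
    perplexity: float = 30,
    label_name: str = "label",
) -> LISIResult:
    """Per-sample Localized Inverse Simpson Index of label mixing.

    For each sample, Gaussian kernel weights over its 3*perplexity nearest
    neighbors are tuned to the target perplexity; LISI is the inverse
    Simpson index 1 / sum_l p_l^2 of the kernel-weighted label proportions.
    Bounded by 1 and the number of categories.
    """
    if isinstance(coords, pd.DataFrame):
        ids = list(coords.index)
        X = coords.to_numpy(dtype=float)
    else:
        X = np.asarray(coords, dtype=float)
        ids = list(range(X.shape[0]))
    labels = pd.Series(np.asarray(labels), index=ids)
    n = X.shape[0]
    if n < 2:
        raise ValueError("LISI needs at least 2 samples")
    if perplexity >= n / 3:
        raise ValueError(f"perplexity {perplexity} too large for n={n} (need < n/3)")
    cats = pd.unique(labels)
    cat_codes = labels.map({c: i for i, c in enumerate(cats)}).to_numpy()
    k = min(int(3 * perplexity), n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    dists, idx = nn.kneighbors(X)
    dists, idx = dists[:, 1:], idx[:, 1:]  # drop self
    out = np.empty(n)
    for i in range(n):
        p = _tune_kernel(dists[i], perplexity)
        props = np.bincount(cat_codes[idx[i]], weights=p, minlength=len(cats))
        out[i] = 1.0 / float((props**2).sum())
    return LISIResult(
        per_sample_lisi=pd.Series(out, index=ids),
        label_name=label_name,
        perplexity=perplexity,
        n_categories=len(cats),
    )


def gene_count_sweep(
    cohort_matrices: Sequence[ExpressionMatrix],
    stable_genes: Sequence[str],
    gene_counts: Iterable[int],
    labels: dict,
    n_train: int | None = None,
    n_components: int = 4,
    perplexity: float = 30,
    seed: int | None = None,
    er_anchor_gene: str | None = None,
) -> pd.DataFrame:
    """LISI as a function of the number of variable genes.

    For each count, rerun selection -> normalization -> embedding on the
    pooled cohorts and report the median LISI on PC1/PC2 and PC3/PC4 for
    every label set in ``labels`` (mapping label name -> sample-indexed
    Series, e.g. cohort and ER status).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for count in gene_counts:
        selection = select_feature_genes(cohort_matrices, stable_genes, n_variable=count)
        pooled = pd.concat(
            [m.to_frame().reindex(selection.feature_genes) for m in cohort_matrices],
            axis=1,
        )
        normalized = rank_normalize(ExpressionMatrix.from_frame(pooled), selection)
        ids = list(normalized.sample_ids)
        if n_train is not None and n_train < len(ids):
            tr = np.sort(rng.choice(len(ids), size=n_train, replace=False))
        else:
            tr = np.arange(len(ids))
        train = NormalizedMatrix(
            gene_ids=normalized.gene_ids,
            sample_ids=[ids[i] for i in tr],
            values=normalized.values[:, tr],
            stable_genes=normalized.stable_genes,
        )
        model, _ = fit_embedding(train, n_components=n_components,
                                 er_anchor_gene=er_anchor_gene)
        scores = transform(model, normalized).to_frame()
        for label_name, series in labels.items():
            lab = pd.Series(series).reindex(scores.index)
            for plane, cols in (("PC1/PC2", ["PC1", "PC2"]), ("PC3/PC4", ["PC3", "PC4"])):
                res = lisi(scores[cols], lab, perplexity=perplexity, label_name=label_name)
                rows.append(
                    {
                        "n_variable_genes": count,
                        "label": label_name,
                        "plane": plane,
                        "median_lisi": res.median,
                        "mean_lisi": res.mean,
                    }
                )
    return pd.DataFrame.from_records(rows)


def _knn_sets(coords: np.ndarray, probe_idx: np.ndarray, k: int) -> list:
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords[probe_idx])
    sets = []
    for row, p in zip(idx, probe_idx):
        neigh = [int(i) for i in row if int(i) != int(p)][:k]
        sets.append(set(neigh))
    return sets


def knn_jaccard(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    probe_idx: np.ndarray,
    k: int,
) -> np.ndarray:
    """Jaccard overlap of each probe's k-NN set in two embeddings of the
    same samples."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if k >= coords_a.shape[0]:
        raise ValueError("k must be smaller than the number of samples")
    sets_a = _knn_sets(coords_a, probe_idx, k)
    sets_b = _knn_sets(coords_b, probe_idx, k)
    out = np.empty(len(probe_idx))
    for i, (sa, sb) in enumerate(zip(sets_a, sets_b)):
        out[i] = len(sa & sb) / len(sa | sb)
    return out


def jaccard_stability(
    normalized: NormalizedMatrix,
    reference_model: EmbeddingModel,
    reference_scores: SampleScores,
    n_train: int = 1000,
    n_seeds: int = 25,
    n_probes: int = 1000,
    k_neighbors: int = 50,
    cohort_labels: pd.Series | None = None,
    seed: int | None = None,
    components: Sequence[str] = ("PC3", "PC4"),
) -> StabilityReport:
    """Neighborhood agreement between the reference embedding and refits.

    For each of ``n_seeds`` resampled training subsets of size ``n_train``,
    refit the uncentered PCA, align signs to the reference anchors, embed
    all samples and compare each probe sample's k-nearest-neighbor set (in
    the PC3/PC4 plane) to the reference.  Probes are drawn per cohort when
    cohort labels are given.
    """
    ids = list(normalized.sample_ids)
    n = len(ids)
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the sample count")
    rng = np.random.default_rng(seed)
    cols = [reference_scores.component_labels.index(c) for c in components]
    ref_coords = reference_scores.coordinates[:, cols]

    if cohort_labels is not None:
        cohort_labels = pd.Series(cohort_labels).reindex(ids)
        probe_idx = []
        for c in cohort_labels.dropna().unique():
            pool = np.flatnonzero((cohort_labels == c).to_numpy())
            take = min(n_probes, pool.size)
            probe_idx.append(rng.choice(pool, size=take, replace=False))
        probe_idx = np.concatenate(probe_idx)
    else:
        probe_idx = rng.choice(n, size=min(n_probes, n), replace=False)

    anchor_rules = {
        label: anchor
        for label, anchor in zip(reference_model.component_labels,
                                 reference_model.sign_anchor)
    }
    values = []
    for _ in range(n_seeds):
        tr = np.sort(rng.choice(n, size=min(n_train, n), replace=False))
        train = NormalizedMatrix(
            gene_ids=normalized.gene_ids,
            sample_ids=[ids[i] for i in tr],
            values=normalized.values[:, tr],
            stable_genes=normalized.stable_genes,
        )
        model, _ = fit_embedding(train, n_components=reference_model.n_components)
        model = align_signs(model, anchor_rules)
        new_coords = transform(model, normalized).coordinates[:, cols]
        values.append(knn_jaccard(ref_coords, new_coords, probe_idx, k_neighbors))
    per_probe = np.mean(np.column_stack(values), axis=1)
    return StabilityReport(
        per_probe_jaccard=pd.Series(per_probe, index=[ids[i] for i in probe_idx]),
        k_neighbors=k_neighbors,
        n_seeds=n_seeds,
    )


def _hex_assign(x: np.ndarray, y: np.ndarray, size: float):
    """Pointy-top hexagonal binning via axial coordinates with cube rounding."""
    q = (np.sqrt(3) / 3 * x - 1.0 / 3 * y) / size
    r = (2.0 / 3 * y) / size
    # cube round
    xs, zs = q, r
    ys = -xs - zs
    rx, ry, rz = np.round(xs), np.round(ys), np.round(zs)
    dx, dy, dz = np.abs(rx - xs), np.abs(ry - ys), np.abs(rz - zs)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(int), rz.astype(int)


def _hex_center(q: np.ndarray, r: np.ndarray, size: float):
    x = size * np.sqrt(3) * (q + r / 2.0)
    y = size * 1.5 * r
    return x, y


def hexbin_scores(
    scores: SampleScores | pd.DataFrame,
    sample_values: pd.Series,
    hex_size: float | None = None,
    components: Sequence[str] = ("PC3", "PC4"),
    max_cell_fraction: float = 0.05,
) -> HexGrid:
    """Hexagonally bin (PC3, PC4) and average a per-sample value per cell.

    Every sample lands in exactly one cell, so the count-weighted mean of
    the cell means reproduces the global mean.  When ``hex_size`` is not
    given it starts at 1/8 of the coordinate span and shrinks until the
    densest cell holds at most ``max_cell_fraction`` of the samples.
    """
    frame = scores.to_frame() if isinstance(scores, SampleScores) else scores
    if len(frame) == 0:
        return HexGrid(
            hex_size=float(hex_size or 1.0),
            cells=pd.DataFrame(columns=["x", "y", "count", "mean_value"]),
            assignments=pd.Series(dtype=object),
        )
    missing = [s for s in frame.index if s not in sample_values.index]
    if missing:
        raise KeyError(f"values missing for samples: {missing[:5]}")
    x = frame[components[0]].to_numpy(dtype=float)
    y = frame[components[1]].to_numpy(dtype=float)
    vals = sample_values.reindex(frame.index).to_numpy(dtype=float)

    n = len(frame)
    if hex_size is None:
        span = max(x.max() - x.min(), y.max() - y.min(), 1e-12)
        hex_size = span / 8
        limit = max(1, int(np.ceil(max_cell_fraction * n)))
        for _ in range(20):
            q, r = _hex_assign(x, y, hex_size)
            _, counts = np.unique(np.column_stack([q, r]), axis=0, return_counts=True)
            if counts.max() <= limit:
                break
            hex_size *= 0.75
    q, r = _hex_assign(x, y, hex_size)
    keys = pd.Series([f"{a},{b}" for a, b in zip(q, r)], index=frame.index)
    df = pd.DataFrame({"q": q, "r": r, "value": vals, "key": keys.to_numpy()})
    grouped = df.groupby("key").agg(
        q=("q", "first"), r=("r", "first"),
        count=("value", "size"), mean_value=("value", "mean"),
    )
    cx, cy = _hex_center(grouped["q"].to_numpy(), grouped["r"].to_numpy(), hex_size)
    cells = pd.DataFrame(
        {"x": cx, "y": cy, "count": grouped["count"].to_numpy(),
         "mean_value": grouped["mean_value"].to_numpy()},
        index=grouped.index,
    )
    gradient = None
    if len(cells) >= 3:
        A = np.column_stack([np.ones(len(cells)), cells["x"], cells["y"]])
        w = np.sqrt(cells["count"].to_numpy(dtype=float))
        coef, *_ = np.linalg.lstsq(A * w[:, None], cells["mean_value"].to_numpy() * w,
                                   rcond=None)
        gradient = coef[1:]
    return HexGrid(hex_size=float(hex_size), cells=cells, assignments=keys,
                   gradient=gradient)


def missing_gene_sensitivity(
    model: EmbeddingModel,
    samples: ExpressionMatrix,
    fractions: Sequence[float],
    selection: GeneSelection | None = None,
    k_neighbors: int = 10,
    components: Sequence[str] = ("PC3", "PC4"),
) -> pd.DataFrame:
    """Projection displacement when the top PC3/PC4-loading genes go missing.

    For each fraction f, the feature genes with the largest
    max(|PC3 loading|, |PC4 loading|) are removed from every sample; each
    sample is re-normalized among its remaining genes, missing genes are
    zero-filled and the sample re-projected.  Reports the mean Euclidean
    displacement in (PC3, PC4) and the k-NN Jaccard against the intact
    projection.
    """
    for f in fractions:
        if not 0 <= f < 1:
            raise ValueError(f"fraction must be in [0, 1), got {f}")
    if selection is None:
        selection = GeneSelection(
            variable_genes=[g for g in model.feature_genes
                            if g not in set(model.stable_genes)],
            stable_genes=model.stable_genes,
        )
    cols = [model.component_labels.index(c) for c in components]
    importance = np.abs(model.loadings[:, cols]).max(axis=1)
    order = np.argsort(-importance)  # most important first
    frame = samples.to_frame()

    def project_all(drop: set) -> np.ndarray:
        coords = np.empty((samples.n_samples, len(cols)))
        for j, sid in enumerate(samples.sample_ids):
            col = frame[sid].drop(labels=[g for g in drop if g in frame.index])
            normalized = normalize_sample(col, selection)
            coords[j] = project(model, normalized)[cols]
        return coords

    baseline = project_all(set())
    rows = []
    for f in sorted(set(fractions)):
        n_drop = int(round(f * len(model.feature_genes)))
        drop = {model.feature_genes[i] for i in order[:n_drop]}
        degraded = project_all(drop)
        disp = np.sqrt(((degraded - baseline) ** 2).sum(axis=1))
        if k_neighbors < samples.n_samples:
            jac = knn_jaccard(baseline, degraded,
                              np.arange(samples.n_samples), k_neighbors)
            mean_jac = float(jac.mean())
        else:
            mean_jac = np.nan
        rows.append(
            {"fraction": f, "n_genes_removed": n_drop,
             "mean_displacement": float(disp.mean()),
             "max_displacement": float(disp.max()),
             "mean_knn_jaccard": mean_jac}
        )
    return pd.DataFrame.from_records(rows)
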