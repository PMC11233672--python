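"""Variable-gene selection and stable-gene rank normalization.

The normalization mimics qPCR reference-gene calibration: within each
sample, the feature genes are ranked from lowest to highest expression and
every rank is divided by the mean rank of a panel of housekeeping ("stable")
genes whose expression varies little across tumors.  Because only
within-sample ranks are used, any strictly monotone per-sample distortion
(platform dynamic-range compression, library-size scaling, log-base
changes) is removed exactly, which is what makes microarray and RNA-seq
samples directly comparable afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ExpressionMatrix

__all__ = [
    "GeneSelection",
    "NormalizedMatrix",
    "compute_cv",
    "select_feature_genes",
    "rank_normalize",
    "normalize_sample",
    "stable_gene_count_sweep",
]


@dataclass
class GeneSelection:
    """Feature genes of the embedding: top-CV variable genes + stable panel.

    ``feature_genes`` is the concatenation variable + stable; with the
    defaults (1000 variable, 44 stable) it has 1044 entries.
    """

    variable_genes: list
    stable_genes: list
    cv_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.variable_genes = list(self.variable_genes)
        self.stable_genes = list(self.stable_genes)
        overlap = set(self.variable_genes) & set(self.stable_genes)
        if overlap:
            raise ValueError(f"variable and stable gene lists overlap: {sorted(overlap)[:5]}")

    @property
    def feature_genes(self) -> list:
        return self.variable_genes + self.stable_genes

    @property
    def n_features(self) -> int:
        return len(self.variable_genes) + len(self.stable_genes)


@dataclass
class NormalizedMatrix:
    """Rank-normalized expression: per-sample rank / mean stable-gene rank.

    All values are strictly positive and for every sample the mean of the
    stable-gene values is 1 by construction.
    """

    gene_ids: list
    sample_ids: list
    values: np.ndarray
    stable_genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("normalized matrix shape mismatch")
        if np.any(self.values <= 0):
            raise ValueError("normalized values must be strictly positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def sample(self, sample_id: str) -> pd.Series:
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.values[:, j], index=self.gene_ids, name=sample_id)


def compute_cv(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene coefficient of variation, CV = sd / mean.

    The standard deviation uses the n-1 denominator.  Genes whose mean is
    exactly zero get NaN (undefined CV) and are excluded from variable-gene
    ranking downstream.

    Raises
    ------
    ValueError
        If the matrix has fewer than 2 samples (sd undefined).
    """
    if matrix.n_samples < 2:
        raise ValueError("CV requires at least 2 samples")
    means = matrix.values.mean(axis=1)
    sds = matrix.values.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means != 0, sds / means, np.nan)
    return pd.Series(cv, index=matrix.gene_ids, name="cv")


def select_feature_genes(
    cohort_matrices: Sequence[ExpressionMatrix],
    stable_genes: Sequence[str],
    n_variable: int = 1000,
    cohort_names: Sequence[str] | None = None,
) -> GeneSelection:
    """Pick the ``n_variable`` genes with highest average CV across cohorts.

    The candidate pool is the genes shared by every cohort minus the stable
    panel; per-cohort CVs are averaged without cohort-size weighting, the
    top ``n_variable`` are kept (ties broken by gene identifier so the
    result is invariant to gene/sample order), and the stable genes are
    appended last.  Genes with zero mean in any cohort are dropped before
    ranking because their CV is undefined.
    """
    if not cohort_matrices:
        raise ValueError("at least one cohort matrix is required")
    stable_genes = list(stable_genes)
    if cohort_names is None:
        cohort_names = [f"cohort{i + 1}" for i in range(len(cohort_matrices))]

    gene_sets = [set(m.gene_ids) for m in cohort_matrices]
    for g in stable_genes:
        for name, gs in zip(cohort_names, gene_sets):
            if g not in gs:
                raise ValueError(f"stable gene {g!r} absent from cohort {name!r}")

    shared = set.intersection(*gene_sets)
    candidates = sorted(shared - set(stable_genes))

    cv_cols = {}
    for name, m in zip(cohort_names, cohort_matrices):
        cv_cols[name] = compute_cv(m).reindex(candidates)
    cv_table = pd.DataFrame(cv_cols)
    # undefined CV (zero-mean gene) in any cohort disqualifies the gene
    valid = cv_table.dropna()
    mean_cv = valid.mean(axis=1)
    if len(valid) < n_variable:
        raise ValueError(
            f"only {len(valid)} shared genes with defined CV, need {n_variable}"
        )
    order = sorted(valid.index, key=lambda g: (-mean_cv[g], g))
    variable = order[:n_variable]

    table = cv_table.loc[order].copy()
    table["mean_cv"] = mean_cv.reindex(order)
    table["rank"] = np.arange(1, len(order) + 1)
    table.index.name = "gene"
    return GeneSelection(variable_genes=variable, stable_genes=stable_genes, cv_table=table)


def _rank_columns(values: np.ndarray) -> np.ndarray:
    """Rank each column lowest-to-highest, average ranks for ties."""
    return rankdata(values, axis=0, method="average")


def rank_normalize(matrix: ExpressionMatrix, selection: GeneSelection) -> NormalizedMatrix:
    """Rank the feature genes per sample and divide by the stable-gene mean rank.

    All feature genes must be present; projection of degraded samples with
    missing genes goes through :func:`normalize_sample` (re-rank among the
    available genes) followed by zero-fill at projection time.
    """
    present = set(matrix.gene_ids)
    missing = [g for g in selection.feature_genes if g not in present]
    if missing:
        raise KeyError(
            f"feature genes missing from matrix: {missing[:5]} — degraded samples "
            "must be normalized per-sample (normalize_sample) and zero-filled at projection"
        )
    sub = matrix.subset_genes(selection.feature_genes)
    ranks = _rank_columns(sub.values)
    stable_idx = [selection.feature_genes.index(g) for g in selection.stable_genes]
    divisor = ranks[stable_idx, :].mean(axis=0)
    return NormalizedMatrix(
        gene_ids=selection.feature_genes,
        sample_ids=sub.sample_ids,
        values=ranks / divisor,
        stable_genes=list(selection.stable_genes),
    )


def normalize_sample(sample: pd.Series, selection: GeneSelection) -> pd.Series:
    """Rank-normalize a single sample among its *available* feature genes.

    Genes of the feature panel absent from ``sample`` are simply left out
    (they contribute 0 at projection); the stable divisor uses whichever
    stable genes are available.
    """
    index = set(sample.index)
    available = [g for g in selection.feature_genes if g in index]
    if not available:
        raise ValueError("sample shares no genes with the feature panel")
    stable_avail = [g for g in selection.stable_genes if g in index]
    if not stable_avail:
        raise ValueError("sample has no stable genes; cannot compute the rank divisor")
    vals = sample.reindex(available).to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("sample contains non-finite values")
    ranks = rankdata(vals, method="average")
    positions = {g: i for i, g in enumerate(available)}
    divisor = np.mean([ranks[positions[g]] for g in stable_avail])
    return pd.Series(ranks / divisor, index=available, name=sample.name)


def _spearman_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of two equal-shape matrices."""
    ra = rankdata(a, axis=1)
    rb = rankdata(b, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    out = np.full(a.shape[0], np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def stable_gene_count_sweep(
    matrix: ExpressionMatrix,
    selection: GeneSelection,
    subset_sizes: Iterable[int],
    n_draws: int = 25,
    seed: int | None = None,
    quantiles: Sequence[float] = (0.1,),
) -> pd.DataFrame:
    """How few stable genes still reproduce the full-panel normalization.

    For each subset size, draw random subsets of the stable panel, use only
    those genes as the rank divisor, and correlate (Spearman, across
    samples) every variable gene's renormalized values against the
    full-panel normalization.  Reports the minimum and requested quantiles
    of the per-gene correlations for each draw.  Ranks never change — only
    the per-sample divisor does — so correlations below 1 quantify divisor
    instability alone.
    """
    rng = np.random.default_rng(seed)
    n_stable = len(selection.stable_genes)
    sizes = list(subset_sizes)
    for s in sizes:
        if s < 2:
            raise ValueError(f"stable subset size must be >= 2, got {s}")
        if s > n_stable:
            raise ValueError(f"subset size {s} exceeds stable panel size {n_stable}")

    sub = matrix.subset_genes(selection.feature_genes)
    ranks = _rank_columns(sub.values)
    stable_idx = np.array([selection.feature_genes.index(g) for g in selection.stable_genes])
    var_idx = np.arange(len(selection.variable_genes))
    full_divisor = ranks[stable_idx, :].mean(axis=0)
    full_norm = ranks[var_idx, :] / full_divisor

    records = []
    for size in sizes:
        for draw in range(n_draws):
            chosen = rng.choice(stable_idx, size=size, replace=False)
            divisor = ranks[chosen, :].mean(axis=0)
            renorm = ranks[var_idx, :] / divisor
            corr = _spearman_rows(renorm, full_norm)
            corr = corr[np.isfinite(corr)]
            rec = {"subset_size": size, "draw": draw, "min_corr": float(np.min(corr))}
            for q in quantiles:
                rec[f"q{int(round(q * 100))}"] = float(np.quantile(corr, q))
            records.append(rec)
    return pd.DataFrame.from_records(records)
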