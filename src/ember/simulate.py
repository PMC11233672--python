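"""Synthetic two-cohort breast-cancer-like expression data with ground truth.

The generator produces log-scale expression for two cohorts sharing a gene
universe but measured on different "platforms".  Structure:

- five latent subtype groups (luminal-A/B-like, HER2-like, basal-like,
  normal-like) forming a continuum: each sample draws continuous program
  activities around its subtype's means;
- four gene programs (ER signaling, proliferation, EMT, HER2) whose
  loadings times the activities produce the biological variation;
- a designated low-variance stable-gene panel (no program loadings, small
  noise) emulating the housekeeping genes used as rank divisor;
- a platform/batch model per cohort: a per-gene additive bias (probe
  effects, constant across samples — this is what survives rank
  normalization and lands in PC1/PC2) plus a sample-wise affine map and a
  strictly monotone softplus compression emulating microarray dynamic-range
  saturation (removed exactly by ranking).

Everything is reproducible bitwise from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneSetCollection

__all__ = [
    "ProgramSpec",
    "BatchSpec",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate",
    "degrade",
]

SUBTYPES = ("LumA", "LumB", "Her2", "Basal", "Normal")


@dataclass
class ProgramSpec:
    """A gene program: how many genes carry it and how strongly."""

    n_genes: int
    effect: float
    # per-subtype mean activity, in SUBTYPES order
    subtype_means: tuple
    within_subtype_sd: float = 1.2


@dataclass
class BatchSpec:
    """Per-cohort platform model.

    ``gene_bias_sd``: sd of the per-gene additive probe bias (survives
    ranking).  ``offset``/``scale``/``compress`` parameterize the
    sample-wise strictly monotone map
    y = offset + scale*x + compress*softplus(x - center) (erased by
    ranking).
    """

    gene_bias_sd: float = 0.0
    offset: float = 0.0
    scale: float = 1.0
    compress: float = 0.0
    center: float = 6.0

    def monotone(self, x: np.ndarray) -> np.ndarray:
        return self.offset + self.scale * x + self.compress * np.logaddexp(0.0, x - self.center)


def _default_programs() -> dict:
    return {
        "er": ProgramSpec(
            n_genes=150, effect=1.0,
            subtype_means=(2.0, 1.6, -0.8, -2.0, 0.3),
        ),
        "proliferation": ProgramSpec(
            n_genes=120, effect=0.8,
            subtype_means=(-1.0, 1.5, 0.8, 1.8, -1.8),
        ),
        "emt": ProgramSpec(
            n_genes=80, effect=0.6,
            subtype_means=(0.8, -0.8, -0.3, 0.5, 1.5),
        ),
        "her2": ProgramSpec(
            n_genes=50, effect=0.7,
            subtype_means=(-0.5, 0.0, 2.0, -0.5, -0.5),
        ),
    }


def _default_batches() -> dict:
    return {
        # RNA-seq-like reference platform
        "cohortA": BatchSpec(),
        # microarray-like: probe biases + affine + dynamic-range compression
        "cohortB": BatchSpec(gene_bias_sd=1.8, offset=1.5, scale=0.85, compress=0.6),
    }


@dataclass
class SimulationConfig:
    n_samples_per_cohort: int = 600
    n_genes: int = 2000
    n_stable_genes: int = 44
    subtype_proportions: tuple = (0.40, 0.20, 0.10, 0.20, 0.10)
    programs: dict = field(default_factory=_default_programs)
    batches: dict = field(default_factory=_default_batches)
    baseline_mean: float = 6.0
    baseline_sd: float = 1.5
    noise_sd_range: tuple = (0.2, 0.8)
    stable_noise_sd: float = 0.05
    seed: int = 20240709

    def __post_init__(self) -> None:
        # accept plain dicts (e.g. parsed from a YAML config) for the nested specs
        self.programs = {
            k: (v if isinstance(v, ProgramSpec) else ProgramSpec(**v))
            for k, v in self.programs.items()
        }
        self.batches = {
            k: (v if isinstance(v, BatchSpec) else BatchSpec(**v))
            for k, v in self.batches.items()
        }
        self.subtype_proportions = tuple(self.subtype_proportions)
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")
        if len(self.subtype_proportions) != len(SUBTYPES):
            raise ValueError(f"need {len(SUBTYPES)} subtype proportions")
        n_program = sum(p.n_genes for p in self.programs.values())
        if n_program + self.n_stable_genes >= self.n_genes:
            raise ValueError("programs + stable genes exceed the gene count")
        if self.stable_noise_sd <= 0 or self.noise_sd_range[0] <= 0:
            raise ValueError("noise sds must be positive")


@dataclass
class SimulatedStudy:
    cohorts: list  # of ExpressionMatrix
    truth: pd.DataFrame  # sample_id-indexed: cohort, subtype, er_status, activities
    stable_gene_ids: list
    program_genes: dict  # program name -> gene list
    er_hub_gene: str
    config: SimulationConfig
    removed_genes: dict = field(default_factory=dict)  # cohort -> removed gene list

    @property
    def cohort_names(self) -> list:
        return [m.scale_tag for m in self.cohorts]

    def program_collection(self) -> GeneSetCollection:
        sets = dict(self.program_genes)
        sets["stable"] = list(self.stable_gene_ids)
        return GeneSetCollection(sets=sets)

    def labels(self, column: str) -> pd.Series:
        return self.truth[column]


def _gene_ids(config: SimulationConfig) -> tuple[list, dict, list]:
    programs = {}
    for name, spec in config.programs.items():
        prefix = name[:3].upper()
        programs[name] = [f"{prefix}{i + 1:04d}" for i in range(spec.n_genes)]
    stable = [f"STAB{i + 1:03d}" for i in range(config.n_stable_genes)]
    n_bg = config.n_genes - config.n_stable_genes - sum(
        len(g) for g in programs.values()
    )
    background = [f"BG{i + 1:05d}" for i in range(n_bg)]
    all_genes = [g for genes in programs.values() for g in genes] + background + stable
    return all_genes, programs, stable


def simulate(config: SimulationConfig | None = None) -> SimulatedStudy:
    """Draw a two-cohort study with known subtype/program ground truth."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genes, program_genes, stable = _gene_ids(config)
    gene_pos = {g: i for i, g in enumerate(genes)}
    p = len(genes)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=p)
    noise_sd = rng.uniform(*config.noise_sd_range, size=p)
    stable_idx = np.array([gene_pos[g] for g in stable])
    noise_sd[stable_idx] = config.stable_noise_sd
    # park stable genes mid-range so their ranks sit away from the extremes
    baseline[stable_idx] = rng.normal(config.baseline_mean, 0.8, size=len(stable))

    # program loading matrix (genes x programs)
    prog_names = list(config.programs)
    L = np.zeros((p, len(prog_names)))
    hub_gene = None
    for j, name in enumerate(prog_names):
        spec = config.programs[name]
        idx = np.array([gene_pos[g] for g in program_genes[name]])
        signs = rng.choice([1.0, -1.0], size=idx.size, p=[0.8, 0.2])
        mags = rng.uniform(0.5, 1.5, size=idx.size) * spec.effect
        L[idx, j] = signs * mags
        if name == "er":
            # hub gene: strongest positively-loaded ER gene, the synthetic ESR1
            pos = idx[signs > 0]
            hub_gene = genes[int(pos[np.argmax(L[pos, j])])]

    subtype_means = np.array(
        [config.programs[name].subtype_means for name in prog_names]
    ).T  # subtypes x programs
    within_sd = np.array(
        [config.programs[name].within_subtype_sd for name in prog_names]
    )

    cohorts = []
    truth_rows = []
    for cohort_name, batch in config.batches.items():
        n = config.n_samples_per_cohort
        subtype_idx = rng.choice(len(SUBTYPES), size=n, p=config.subtype_proportions)
        activities = (
            subtype_means[subtype_idx]
            + rng.normal(0.0, 1.0, size=(n, len(prog_names))) * within_sd
        )
        noise = rng.normal(0.0, 1.0, size=(p, n)) * noise_sd[:, None]
        base = baseline[:, None] + L @ activities.T + noise
        gene_bias = (
            rng.normal(0.0, batch.gene_bias_sd, size=p)
            if batch.gene_bias_sd > 0
            else np.zeros(p)
        )
        gene_bias[stable_idx] = 0.0  # housekeeping probes are well behaved
        values = batch.monotone(base + gene_bias[:, None])
        sample_ids = [f"{cohort_name}_S{i + 1:04d}" for i in range(n)]
        cohorts.append(
            ExpressionMatrix(
                gene_ids=genes, sample_ids=sample_ids, values=values,
                scale_tag=cohort_name,
            )
        )
        for i, sid in enumerate(sample_ids):
            row = {
                "sample_id": sid,
                "cohort": cohort_name,
                "subtype": SUBTYPES[subtype_idx[i]],
                "er_status": "ER+" if activities[i, prog_names.index("er")] > 0 else "ER-",
            }
            for j, name in enumerate(prog_names):
                row[f"activity_{name}"] = activities[i, j]
            truth_rows.append(row)

    truth = pd.DataFrame.from_records(truth_rows).set_index("sample_id")
    return SimulatedStudy(
        cohorts=cohorts,
        truth=truth,
        stable_gene_ids=stable,
        program_genes=program_genes,
        er_hub_gene=hub_gene,
        config=config,
    )


def degrade(
    study: SimulatedStudy,
    missing_fraction: float,
    dropout_rule: str = "random",
    loading_importance: pd.Series | None = None,
    seed: int | None = None,
) -> SimulatedStudy:
    """Remove a fraction of genes from every cohort matrix.

    ``dropout_rule`` is "random" (uniform without replacement) or
    "top-loading" (remove the genes with the largest values of
    ``loading_importance``, e.g. max |PC3/PC4 loading| from a fitted
    model).  The removed genes are recorded per cohort.  Removing the whole
    stable panel is refused because nothing could be normalized afterwards.
    """
    if not 0 <= missing_fraction < 1:
        raise ValueError("missing fraction must be in [0, 1)")
    if missing_fraction == 0:
        return replace(study, removed_genes={})
    rng = np.random.default_rng(seed)
    new_cohorts = []
    removed = {}
    for m in study.cohorts:
        n_remove = int(round(missing_fraction * m.n_genes))
        if dropout_rule == "random":
            drop_idx = rng.choice(m.n_genes, size=n_remove, replace=False)
            drop = {m.gene_ids[i] for i in drop_idx}
        elif dropout_rule == "top-loading":
            if loading_importance is None:
                raise ValueError("top-loading rule needs loading_importance")
            ranked = loading_importance.reindex(m.gene_ids).fillna(0.0)
            drop = set(ranked.sort_values(ascending=False).index[:n_remove])
        else:
            raise ValueError(f"unknown dropout rule {dropout_rule!r}")
        if set(study.stable_gene_ids) <= drop:
            raise ValueError("refusing to remove every stable gene")
        keep = [g for g in m.gene_ids if g not in drop]
        new_cohorts.append(m.subset_genes(keep))
        removed[m.scale_tag] = sorted(drop)
    return replace(study, cohorts=new_cohorts, removed_genes=removed)
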