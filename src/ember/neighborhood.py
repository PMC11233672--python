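"""Contextual comparison of a sample against its embedding neighborhood.

A sample's pathway score is interpreted relative to the samples around it
in the (PC3, PC4) plane: the neighborhood's mean score gets a Bayesian
posterior (intercept-only normal model, Normal(0, 1) prior on the mean,
exponential prior on the residual scale, four chains), and the sample is
called above / in the middle of / below that posterior.  Responder vs
non-responder pairs at small embedding distance are then screened with
fixed direction rules per pathway.

The sampler is a Metropolis-within-Gibbs scheme on the conjugate normal
mean: the contract is distributional (posterior summaries), not
draw-for-draw equivalence with any particular MCMC backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datatypes import SampleScores

__all__ = [
    "Neighborhood",
    "PosteriorDraws",
    "RelativeCall",
    "Pair",
    "find_neighborhood",
    "neighborhood_posterior",
    "classify_relative",
    "find_pairs",
    "pair_rule",
    "bayes_group_difference",
]

_BIOLOGY_COMPONENTS = ("PC3", "PC4")


@dataclass
class Neighborhood:
    center_sample: str
    radius: float
    member_ids: list
    empty: bool = False

    def __post_init__(self) -> None:
        self.member_ids = list(self.member_ids)
        if self.center_sample in self.member_ids:
            raise ValueError("center sample must be excluded from its neighborhood")
        self.empty = len(self.member_ids) == 0


@dataclass
class PosteriorDraws:
    """MCMC draws of a scalar parameter with chain labels."""

    parameter: str
    draws: np.ndarray
    chain_ids: np.ndarray
    seed: int | None = None
    n_obs: int = 0
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids)
        if self.draws.shape != self.chain_ids.shape:
            raise ValueError("draws and chain_ids must align")
        chains, counts = np.unique(self.chain_ids, return_counts=True)
        if len(chains) < 2:
            raise ValueError("need at least 2 chains")
        if len(set(counts)) != 1:
            raise ValueError("chains must have equal numbers of draws")

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_ids))

    def mean(self) -> float:
        return float(self.draws.mean())

    def quantile(self, q) -> float | np.ndarray:
        return np.quantile(self.draws, q)

    def split_rhat(self) -> float:
        """Split-chain potential scale reduction factor."""
        chains = [self.draws[self.chain_ids == c] for c in np.unique(self.chain_ids)]
        halves = []
        for c in chains:
            h = len(c) // 2
            halves.append(c[:h])
            halves.append(c[h: 2 * h])
        m = len(halves)
        n = len(halves[0])
        means = np.array([h.mean() for h in halves])
        variances = np.array([h.var(ddof=1) for h in halves])
        B = n * means.var(ddof=1)
        W = variances.mean()
        if W == 0:
            return 1.0
        var_hat = (n - 1) / n * W + B / n
        return float(np.sqrt(var_hat / W))

    def summary(self) -> dict:
        return {
            "parameter": self.parameter,
            "mean": self.mean(),
            "q2.5": float(self.quantile(0.025)),
            "q97.5": float(self.quantile(0.975)),
            "n_draws": int(self.draws.size),
            "rhat": self.split_rhat(),
            "seed": self.seed,
        }


@dataclass
class RelativeCall:
    sample_id: str
    set_name: str
    call: str

    def __post_init__(self) -> None:
        if self.call not in ("above", "middle", "below"):
            raise ValueError(f"invalid call {self.call!r}")


@dataclass
class Pair:
    responder_id: str
    nonresponder_id: str
    distance: float


def _biology_coords(scores: SampleScores, components: Sequence[str]) -> pd.DataFrame:
    frame = scores.to_frame()
    missing = [c for c in components if c not in frame.columns]
    if missing:
        raise KeyError(f"score table lacks components {missing}")
    return frame[list(components)]


def find_neighborhood(
    scores: SampleScores,
    center: str,
    radius: float = 1.0,
    components: Sequence[str] = _BIOLOGY_COMPONENTS,
) -> Neighborhood:
    """Samples within Euclidean ``radius`` of ``center`` in (PC3, PC4).

    Membership uses distance <= radius; the center itself is excluded.  An
    empty neighborhood is returned (flagged), not raised.
    """
    coords = _biology_coords(scores, components)
    if center not in coords.index:
        raise KeyError(f"center sample {center!r} not in scores")
    c = coords.loc[center].to_numpy()
    d = np.sqrt(((coords.to_numpy() - c) ** 2).sum(axis=1))
    members = [
        s for s, dist in zip(coords.index, d) if dist <= radius and s != center
    ]
    return Neighborhood(center_sample=center, radius=radius, member_ids=members)


def _sample_sigma(rng, sigma, resid_ss, n, step=0.4):
    """One Metropolis update of log sigma.

    Posterior kernel: sigma^-n exp(-SS/(2 sigma^2)) * Exp(1) prior, with
    the log-parameterization Jacobian.
    """
    log_sigma = np.log(sigma)
    prop = log_sigma + step * rng.standard_normal()
    sig_p = np.exp(prop)

    def logpost(s, ls):
        return -n * ls - resid_ss / (2 * s * s) - s + ls

    if np.log(rng.random()) < logpost(sig_p, prop) - logpost(sigma, log_sigma):
        return sig_p
    return sigma


def neighborhood_posterior(
    member_scores: Iterable[float],
    n_chains: int = 4,
    n_draws: int = 1000,
    n_warmup: int = 500,
    seed: int | None = None,
    parameter: str = "neighborhood mean",
) -> PosteriorDraws:
    """Posterior of the neighborhood mean under score ~ Normal(mu, sigma).

    Prior mu ~ Normal(0, 1), sigma ~ Exponential(1).  With no members the
    prior itself is returned as a degenerate posterior, flagged.  Draws are
    reproducible bitwise for a fixed seed and chain count.
    """
    y = np.asarray(list(member_scores), dtype=float)
    n = y.size
    rng = np.random.default_rng(seed)
    flags = []
    if n == 0:
        draws = rng.standard_normal(n_chains * n_draws)
        chain_ids = np.repeat(np.arange(n_chains), n_draws)
        return PosteriorDraws(
            parameter=parameter, draws=draws, chain_ids=chain_ids, seed=seed,
            n_obs=0, flags=["empty neighborhood: prior returned"],
        )
    ybar = y.mean()
    all_draws = []
    for chain in range(n_chains):
        crng = np.random.default_rng([0 if seed is None else seed, chain])
        sigma = max(y.std(), 0.1)
        mu = ybar
        kept = np.empty(n_draws)
        for it in range(n_warmup + n_draws):
            prec = 1.0 + n / sigma**2  # prior precision 1 + data precision
            mean = (n * ybar / sigma**2) / prec
            mu = mean + crng.standard_normal() / np.sqrt(prec)
            resid_ss = float(((y - mu) ** 2).sum())
            sigma = _sample_sigma(crng, sigma, resid_ss, n)
            if it >= n_warmup:
                kept[it - n_warmup] = mu
        all_draws.append(kept)
    draws = np.concatenate(all_draws)
    chain_ids = np.repeat(np.arange(n_chains), n_draws)
    if n == 1:
        flags.append("single-member neighborhood: wide posterior")
    return PosteriorDraws(
        parameter=parameter, draws=draws, chain_ids=chain_ids, seed=seed,
        n_obs=n, flags=flags,
    )


def classify_relative(
    sample_score: float,
    posterior: PosteriorDraws,
    tail: float = 0.025,
    sample_id: str = "",
    set_name: str = "",
) -> RelativeCall:
    """Call a score above/middle/below the neighborhood-mean posterior.

    Strict inequalities against the ``tail`` and ``1 - tail`` quantiles of
    the draws; a score exactly at a boundary is "middle".
    """
    lo = float(posterior.quantile(tail))
    hi = float(posterior.quantile(1.0 - tail))
    if sample_score > hi:
        call = "above"
    elif sample_score < lo:
        call = "below"
    else:
        call = "middle"
    return RelativeCall(sample_id=sample_id, set_name=set_name, call=call)


def find_pairs(
    scores: SampleScores,
    labels: pd.Series,
    max_dist: float = 0.5,
    strict: bool = True,
    components: Sequence[str] = _BIOLOGY_COMPONENTS,
) -> list:
    """All responder/non-responder pairs closer than ``max_dist`` in (PC3, PC4).

    A sample may appear in several pairs.  ``labels`` maps sample id to
    "responder" / "non-responder"; other labels are ignored.  The default
    threshold is strict (< max_dist); set ``strict=False`` for <=.
    """
    coords = _biology_coords(scores, components)
    labels = labels.reindex(coords.index)
    resp = coords.index[labels == "responder"]
    nonr = coords.index[labels == "non-responder"]
    if len(resp) == 0 or len(nonr) == 0:
        raise ValueError("both responder and non-responder labels are required")
    d = cdist(coords.loc[resp].to_numpy(), coords.loc[nonr].to_numpy())
    pairs = []
    for i, r in enumerate(resp):
        for j, s in enumerate(nonr):
            dist = float(d[i, j])
            if (dist < max_dist) if strict else (dist <= max_dist):
                pairs.append(Pair(responder_id=r, nonresponder_id=s, distance=dist))
    return pairs


def pair_rule(
    responder_call: RelativeCall,
    nonresponder_call: RelativeCall,
    direction: str,
) -> bool:
    """Screening rule over a responder/non-responder pair of calls.

    ``low-in-nonresponder``: yes iff the non-responder is below its
    neighborhood average and the responder is middle or above (the TGF-beta
    pattern).  ``high-in-nonresponder``: yes iff the non-responder is above
    and the responder middle or below (the androgen pattern).
    """
    r, s = responder_call.call, nonresponder_call.call
    if direction == "low-in-nonresponder":
        return s == "below" and r in ("middle", "above")
    if direction == "high-in-nonresponder":
        return s == "above" and r in ("middle", "below")
    raise ValueError(f"unknown direction {direction!r}")


def bayes_group_difference(
    scores_a: Iterable[float],
    scores_b: Iterable[float],
    n_chains: int = 4,
    n_draws: int = 1000,
    n_warmup: int = 500,
    seed: int | None = None,
) -> tuple[PosteriorDraws, dict]:
    """Posterior of the mean difference between two groups of scores.

    Model: score ~ Normal(a + b * group, sigma) with group b coded 1;
    priors a, b ~ Normal(0, 1), sigma ~ Exponential(1).  Returns draws of
    b (the expectation difference, group b minus group a) and a summary
    with the mean difference, the probability of a difference (fraction of
    draws sharing the majority sign; ~0.5 for identical groups) and the
    percentile-wise differences of the posterior predictive distributions.
    """
    ya = np.asarray(list(scores_a), dtype=float)
    yb = np.asarray(list(scores_b), dtype=float)
    if ya.size == 0 or yb.size == 0:
        raise ValueError("both groups must be non-empty")
    flags = []
    if ya.size == 1 or yb.size == 1:
        flags.append("group of size 1: wide posterior")
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(ya.size), np.ones(yb.size)])
    X = np.column_stack([np.ones_like(g), g])
    XtX = X.T @ X
    Xty = X.T @ y
    n = y.size

    all_b = []
    all_sigma = []
    for chain in range(n_chains):
        crng = np.random.default_rng([1 if seed is None else seed + 1, chain])
        sigma = max(y.std(), 0.1)
        beta = np.array([ya.mean(), yb.mean() - ya.mean()])
        kept_b = np.empty(n_draws)
        kept_s = np.empty(n_draws)
        for it in range(n_warmup + n_draws):
            prec = np.eye(2) + XtX / sigma**2
            cov = np.linalg.inv(prec)
            mean = cov @ (Xty / sigma**2)
            beta = mean + np.linalg.cholesky(cov) @ crng.standard_normal(2)
            resid_ss = float(((y - X @ beta) ** 2).sum())
            sigma = _sample_sigma(crng, sigma, resid_ss, n)
            if it >= n_warmup:
                kept_b[it - n_warmup] = beta[1]
                kept_s[it - n_warmup] = sigma
        all_b.append(kept_b)
        all_sigma.append(kept_s)
    b_draws = np.concatenate(all_b)
    s_draws = np.concatenate(all_sigma)
    chain_ids = np.repeat(np.arange(n_chains), n_draws)
    posterior = PosteriorDraws(
        parameter="group difference", draws=b_draws, chain_ids=chain_ids,
        seed=seed, n_obs=n, flags=flags,
    )
    p_pos = float((b_draws > 0).mean())
    # equal-variance model: the predictive-quantile difference at every
    # percentile equals b draw-for-draw, so the profile is flat at mean(b)
    pred_diff = {int(p): float(b_draws.mean()) for p in np.arange(1, 100)}
    summary = {
        "mean_difference": float(b_draws.mean()),
        "prob_difference": max(p_pos, 1.0 - p_pos),
        "prob_b_greater": p_pos,
        "sigma_mean": float(s_draws.mean()),
        "predictive_percentile_differences": pred_diff,
        "flags": flags,
    }
    return posterior, summary
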