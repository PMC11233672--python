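"""Neighborhood geometry, Bayesian posteriors, relative calls and pair rules."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ember import (
    RelativeCall,
    SampleScores,
    bayes_group_difference,
    classify_relative,
    find_neighborhood,
    find_pairs,
    neighborhood_posterior,
    pair_rule,
)


def _scores(coords, ids=None):
    coords = np.asarray(coords, dtype=float)
    ids = ids or [f"s{i}" for i in range(coords.shape[0])]
    return SampleScores(
        sample_ids=ids, coordinates=coords,
        component_labels=["PC3", "PC4"][: coords.shape[1]]
        if coords.shape[1] == 2
        else [f"PC{i+1}" for i in range(coords.shape[1])],
    )


class TestFindNeighborhood:
    def test_hand_geometry_boundary_inclusive(self):
        sc = _scores([[0, 0], [0.5, 0], [1.0, 0], [1.5, 0]])
        hood = find_neighborhood(sc, "s0", radius=1.0)
        assert hood.member_ids == ["s1", "s2"]  # <= rule includes distance 1.0

    def test_all_far_gives_empty_flagged(self):
        sc = _scores([[0, 0], [2, 0], [0, 2]])
        hood = find_neighborhood(sc, "s0", radius=1.0)
        assert hood.empty and hood.member_ids == []

    def test_radius_zero_empty(self):
        sc = _scores([[0, 0], [0.1, 0]])
        assert find_neighborhood(sc, "s0", radius=0.0).empty


class TestNeighborhoodPosterior:
    def test_prior_recovery_with_no_data(self):
        post = neighborhood_posterior([], n_draws=2000, seed=4)
        n = post.draws.size
        assert abs(post.mean()) < 3 / np.sqrt(n)
        assert post.flags

    def test_large_n_constant_scores(self):
        post = neighborhood_posterior([0.7] * 500, n_draws=1000, seed=4)
        assert abs(post.mean() - 0.7) < 0.02

    def test_seed_reproducible_bitwise(self):
        a = neighborhood_posterior([0.1, 0.5, -0.2], seed=9)
        b = neighborhood_posterior([0.1, 0.5, -0.2], seed=9)
        assert np.array_equal(a.draws, b.draws)

    def test_converges_to_data_mean(self):
        rng = np.random.default_rng(12)
        y = rng.normal(0.3, 0.2, size=10_000)
        post = neighborhood_posterior(y, n_draws=500, seed=5)
        assert abs(post.mean() - y.mean()) < 0.01

    def test_posterior_calibration_against_conjugate_oracle(self):
        """Posterior interval covers the true mean in most simulation repeats,
        and the posterior mean tracks the known-sigma conjugate posterior."""
        mu_star, sigma, n = -0.1, 0.2, 200
        hits = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(100 + rep)
            y = rng.normal(mu_star, sigma, size=n)
            post = neighborhood_posterior(y, n_draws=500, seed=rep)
            lo, hi = post.quantile(0.025), post.quantile(0.975)
            hits += lo <= mu_star <= hi
            # conjugate oracle with sigma known: precision 1 + n/sigma^2
            prec = 1.0 + n / sigma**2
            conj_mean = (y.sum() / sigma**2) / prec
            assert abs(post.mean() - conj_mean) < 4 / np.sqrt(prec)
        assert hits >= 0.9 * reps

    def test_rhat_near_one(self):
        rng = np.random.default_rng(2)
        post = neighborhood_posterior(rng.normal(0, 1, 100), seed=3)
        assert post.split_rhat() < 1.05


class TestClassifyRelative:
    def _post(self):
        return neighborhood_posterior(
            np.random.default_rng(0).normal(0, 1, 200), seed=1
        )

    def test_extreme_score_called_above(self):
        post = self._post()
        assert classify_relative(post.draws.max() + 1, post).call == "above"

    def test_median_called_middle(self):
        post = self._post()
        assert classify_relative(float(np.median(post.draws)), post).call == "middle"

    def test_exact_quantile_is_middle(self):
        post = self._post()
        q = float(post.quantile(0.975))
        assert classify_relative(q, post).call == "middle"

    def test_monotone_in_score(self):
        post = self._post()
        order = {"below": 0, "middle": 1, "above": 2}
        calls = [
            order[classify_relative(s, post).call]
            for s in np.linspace(post.draws.min() - 1, post.draws.max() + 1, 25)
        ]
        assert calls == sorted(calls)


class TestFindPairs:
    def test_single_close_pair(self):
        sc = _scores([[0, 0], [0.3, 0]], ids=["r1", "n1"])
        labels = pd.Series({"r1": "responder", "n1": "non-responder"})
        pairs = find_pairs(sc, labels)
        assert len(pairs) == 1 and pairs[0].distance == pytest.approx(0.3)

    def test_sample_reuse_allowed(self):
        sc = _scores([[0, 0], [0.2, 0], [0.1, 0.1]], ids=["r1", "r2", "n1"])
        labels = pd.Series(
            {"r1": "responder", "r2": "responder", "n1": "non-responder"}
        )
        pairs = find_pairs(sc, labels, max_dist=0.4)
        assert len(pairs) == 2
        assert {p.nonresponder_id for p in pairs} == {"n1"}

    def test_strict_threshold_excludes_boundary(self):
        sc = _scores([[0, 0], [0.5, 0]], ids=["r1", "n1"])
        labels = pd.Series({"r1": "responder", "n1": "non-responder"})
        assert find_pairs(sc, labels, max_dist=0.5, strict=True) == []
        assert len(find_pairs(sc, labels, max_dist=0.5, strict=False)) == 1

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(8)
        coords = rng.normal(0, 1, size=(60, 2))
        labels = pd.Series(
            rng.choice(["responder", "non-responder"], size=60),
            index=[f"s{i}" for i in range(60)],
        )
        sc = _scores(coords, ids=list(labels.index))
        pairs = find_pairs(sc, labels, max_dist=0.5)
        expected = 0
        for i in range(60):
            for j in range(60):
                if labels.iloc[i] == "responder" and labels.iloc[j] == "non-responder":
                    expected += np.linalg.norm(coords[i] - coords[j]) < 0.5
        assert len(pairs) == expected

    def test_rotation_invariance(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(0, 1, size=(40, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        labels = pd.Series(
            ["responder"] * 20 + ["non-responder"] * 20,
            index=[f"s{i}" for i in range(40)],
        )
        a = find_pairs(_scores(coords, list(labels.index)), labels)
        b = find_pairs(_scores(coords @ R.T, list(labels.index)), labels)
        assert {(p.responder_id, p.nonresponder_id) for p in a} == {
            (p.responder_id, p.nonresponder_id) for p in b
        }


class TestPairRule:
    def test_truth_table_matches_enumeration(self):
        calls = ["below", "middle", "above"]
        for r, s in itertools.product(calls, calls):
            rc = RelativeCall(sample_id="r", set_name="p", call=r)
            nc = RelativeCall(sample_id="n", set_name="p", call=s)
            assert pair_rule(rc, nc, "low-in-nonresponder") == (
                s == "below" and r in ("middle", "above")
            )
            assert pair_rule(rc, nc, "high-in-nonresponder") == (
                s == "above" and r in ("middle", "below")
            )

    def test_example_from_rule_definition(self):
        rc = RelativeCall(sample_id="r", set_name="p", call="middle")
        nc = RelativeCall(sample_id="n", set_name="p", call="below")
        assert pair_rule(rc, nc, "low-in-nonresponder")
        rc2 = RelativeCall(sample_id="r", set_name="p", call="below")
        assert not pair_rule(rc2, nc, "low-in-nonresponder")


class TestGroupDifference:
    def test_identical_groups_symmetric(self):
        rng = np.random.default_rng(21)
        y = rng.normal(0, 1, 200)
        post, summary = bayes_group_difference(y, y, seed=6)
        assert abs(summary["mean_difference"]) < 0.1
        assert summary["prob_difference"] < 0.75

    def test_planted_difference_recovered(self):
        rng = np.random.default_rng(22)
        a = rng.normal(0.0, 0.5, 100)
        b = rng.normal(1.5, 0.5, 100)
        post, summary = bayes_group_difference(a, b, seed=7)
        # closed-form two-sample oracle: difference of sample means
        assert abs(summary["mean_difference"] - (b.mean() - a.mean())) < 0.1
        assert abs(summary["mean_difference"] - 1.5) < 0.15
        assert summary["prob_difference"] > 0.99
        # flat predictive percentile profile under equal variances
        diffs = list(summary["predictive_percentile_differences"].values())
        assert max(diffs) - min(diffs) < 1e-12

    def test_label_swap_negates_difference(self):
        rng = np.random.default_rng(23)
        a = rng.normal(0.0, 0.5, 80)
        b = rng.normal(0.8, 0.5, 80)
        _, s1 = bayes_group_difference(a, b, seed=8)
        _, s2 = bayes_group_difference(b, a, seed=8)
        assert s1["mean_difference"] == pytest.approx(-s2["mean_difference"], abs=0.05)

    def test_seed_reproducible(self):
        a, b = [0.1, 0.2, 0.3], [0.5, 0.6]
        p1, _ = bayes_group_difference(a, b, seed=9)
        p2, _ = bayes_group_difference(a, b, seed=9)
        assert np.array_equal(p1.draws, p2.draws)

    def test_singleton_group_flagged(self):
        _, summary = bayes_group_difference([0.5], [0.1, 0.2, 0.3], seed=10)
        assert summary["flags"]
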