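"""STERGM machinery: decomposition, change statistics, MPLE, MH sampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logit

from cownet.covariates import DyadCovariateSet
from cownet.network import DailyNetwork, complement, dyads, from_dyad_vector, random_network
from cownet.stergm import (
    FitError,
    ModelSpec,
    ModelSpecError,
    assess_degeneracy,
    change_statistics,
    decompose_transition,
    fit_mple,
    network_statistics,
    sample_transition,
    simulate_transition,
)
from oracles import direct_transition_mle, enumerate_phase_distribution, triangle_count


def toy_cov(n, seed=0):
    """Small covariate set with variation in every term."""
    rng = np.random.default_rng(seed)
    kin = np.zeros((n, n))
    iu, ju = dyads(n)
    vals = rng.choice([0.0, 0.125, 0.25, 0.5], size=len(iu))
    kin[iu, ju] = vals
    kin += kin.T
    np.fill_diagonal(kin, 1.0)
    kg = np.zeros((n, n), dtype=np.int8)
    kg_vals = (rng.random(len(iu)) < 0.3).astype(np.int8)
    kg[iu, ju] = kg_vals
    kg += kg.T
    parity = tuple(np.resize(["1", "2", "3+"], n))
    return DyadCovariateSet(
        roster=tuple(f"C{k}" for k in range(n)), kinship=kin, kindergarten=kg, parity=parity
    )


class TestModelSpec:
    def test_variants(self):
        assert ModelSpec.m1().variant == "M1"
        assert ModelSpec.m2().variant == "M2"
        assert ModelSpec.m1().dyad_independent
        assert not ModelSpec.m2().dyad_independent

    def test_edges_term_required(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(("kinship",))

    def test_unknown_term_rejected(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(("edges", "gwesp"))


class TestDecomposition:
    def test_identical_networks(self, rng):
        net = random_network(tuple(range(6)), 0.4, rng)
        tr = decompose_transition(net, net)
        np.testing.assert_array_equal(tr.y_plus.adjacency, net.adjacency)
        np.testing.assert_array_equal(tr.y_minus.adjacency, net.adjacency)

    def test_edge_disjoint_networks(self, rng):
        a = random_network(tuple(range(8)), 0.3, rng)
        b = complement(a)
        tr = decompose_transition(a, b)
        assert tr.y_minus.edge_count == 0
        assert tr.y_plus.edge_count == a.n_dyads

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_reconstruction_identity_and_nesting(self, seed):
        rng = np.random.default_rng(seed)
        prev = random_network(tuple(range(10)), 0.4, rng)
        nxt = random_network(tuple(range(10)), 0.4, rng)
        tr = decompose_transition(prev, nxt)
        plus, minus, p, q = (
            tr.y_plus.dyad_vector(),
            tr.y_minus.dyad_vector(),
            prev.dyad_vector(),
            nxt.dyad_vector(),
        )
        assert np.all(minus <= p) and np.all(p <= plus)
        rebuilt = np.where(p == 1, minus, plus)
        np.testing.assert_array_equal(rebuilt, q)

    def test_roster_mismatch_raises(self, rng):
        a = random_network(tuple("abc"), 0.5, rng)
        b = random_network(tuple("abd"), 0.5, rng)
        with pytest.raises(Exception, match="roster"):
            decompose_transition(a, b)


class TestChangeStatistics:
    def test_edges_term_is_one(self):
        cov = toy_cov(5)
        net = from_dyad_vector(np.zeros(10, dtype=int), cov.roster)
        cs = change_statistics(net, (0, 1), ModelSpec(("edges",)), cov)
        assert cs.tolist() == [1.0]

    def test_triangle_stat_on_a_path(self):
        cov = toy_cov(3)
        adj = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=np.int8)
        net = DailyNetwork(adj, cov.roster)
        cs = change_statistics(net, (0, 1), ModelSpec(("edges", "triangles")), cov)
        assert cs[1] == 1.0  # node 2 is the single common neighbor

    def test_parity_and_covariate_terms(self):
        cov = toy_cov(6)
        net = from_dyad_vector(np.zeros(15, dtype=int), cov.roster)
        spec = ModelSpec.m1()
        cs = change_statistics(net, (1, 4), spec, cov)  # parities "2" and "2"
        named = dict(zip(spec.terms, cs))
        assert named["parity_2"] == 2.0
        assert named["parity_match"] == 1.0
        assert named["kinship"] == cov.kinship[1, 4]
        assert named["kindergarten"] == cov.kindergarten[1, 4]

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_triangle_change_equals_toggle_difference(self, seed):
        rng = np.random.default_rng(seed)
        cov = toy_cov(8)
        net = random_network(cov.roster, 0.4, rng)
        spec = ModelSpec(("edges", "triangles"))
        iu, ju = dyads(8)
        for i, j in list(zip(iu, ju)):
            cs = change_statistics(net, (int(i), int(j)), spec, cov)
            on = net.adjacency.copy()
            on[i, j] = on[j, i] = 1
            off = net.adjacency.copy()
            off[i, j] = off[j, i] = 0
            assert cs[1] == triangle_count(on) - triangle_count(off)

    def test_triangle_sufficient_statistic_matches_brute_force(self, rng):
        cov = toy_cov(8)
        net = random_network(cov.roster, 0.5, rng)
        g = network_statistics(net, ModelSpec(("edges", "triangles")), cov)
        assert g[1] == triangle_count(net.adjacency)


class TestMPLE:
    def test_intercept_only_formation_is_logit_of_formed_fraction(self, rng):
        n = 5
        cov = toy_cov(n)
        prev = from_dyad_vector(np.array([1, 0, 0, 0, 0, 0, 0, 0, 1, 0]), cov.roster)
        nxt = from_dyad_vector(np.array([1, 1, 0, 0, 1, 0, 0, 0, 0, 0]), cov.roster)
        fit = fit_mple([decompose_transition(prev, nxt)], ModelSpec(("edges",)), cov)
        # 8 empty dyads, 2 formed; 2 tied dyads, 1 persisted
        assert fit.formation.coefs["edges"] == pytest.approx(logit(2 / 8), abs=1e-6)
        assert fit.persistence.coefs["edges"] == pytest.approx(logit(1 / 2), abs=1e-6)

    def test_matches_direct_transition_likelihood_maximization(self):
        """Dyad-independent MPLE == exact MLE (enumeration + BFGS oracle)."""
        n = 5
        cov = toy_cov(n, seed=3)
        spec = ModelSpec(("edges", "kindergarten"))
        nets = [random_network(cov.roster, 0.5, np.random.default_rng(s)) for s in range(7)]
        transitions = [decompose_transition(a, b) for a, b in zip(nets[:-1], nets[1:])]
        fit = fit_mple(transitions, spec, cov)
        assert fit.converged
        x0 = np.concatenate([fit.formation.coefs.to_numpy(), fit.persistence.coefs.to_numpy()])
        tf, tp, res = direct_transition_mle(transitions, spec, cov, x0=x0 * 0.9)
        np.testing.assert_allclose(fit.formation.coefs.to_numpy(), tf, atol=1e-6)
        np.testing.assert_allclose(fit.persistence.coefs.to_numpy(), tp, atol=1e-6)

    def test_no_formations_flags_separation(self):
        # previous ties partly persist but no empty dyad ever forms a tie:
        # the formation response is constant 0 -> separation, not an exception
        n = 5
        cov = toy_cov(n)
        prev = from_dyad_vector(np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0]), cov.roster)
        nxt = from_dyad_vector(np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0]), cov.roster)
        fit = fit_mple([decompose_transition(prev, nxt)], ModelSpec(("edges",)), cov)
        assert not fit.converged
        assert fit.formation.separation
        assert np.isnan(fit.formation.coefs["edges"])
        assert fit.persistence.converged  # 2 of 4 ties persisted: estimable

    def test_zero_free_dyads_is_a_fit_error(self):
        n = 5
        cov = toy_cov(n)
        empty = from_dyad_vector(np.zeros(10, dtype=int), cov.roster)
        with pytest.raises(FitError, match="free dyads"):
            fit_mple([decompose_transition(empty, empty)], ModelSpec(("edges",)), cov)

    def test_phase_free_dyads_partition_all_dyads(self, rng):
        cov = toy_cov(10)
        prev = random_network(cov.roster, 0.3, rng)
        nxt = random_network(cov.roster, 0.3, rng)
        fit = fit_mple([decompose_transition(prev, nxt)], ModelSpec.m1(), cov)
        assert fit.formation.n_free_dyads + fit.persistence.n_free_dyads == prev.n_dyads

    def test_covariate_roster_mismatch_raises(self, rng):
        cov = toy_cov(5)
        other = random_network(tuple("vwxyz"), 0.5, rng)
        with pytest.raises(FitError):
            fit_mple([decompose_transition(other, other)], ModelSpec.m1(), toy_cov(5, seed=1))


class TestSampler:
    def test_deterministic_given_seed(self, rng):
        cov = toy_cov(8)
        prev = random_network(cov.roster, 0.3, rng)
        theta = pd.Series({"edges": -1.0, "kinship": 1.0})
        spec = ModelSpec(("edges", "kinship"))
        a = sample_transition(prev, theta, theta, spec, cov, 5, seed=42)
        b = sample_transition(prev, theta, theta, spec, cov, 5, seed=42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.adjacency, y.adjacency)

    def test_extreme_negative_coefficients_near_empty_the_network(self, rng):
        # per-dyad tie probability is sigmoid(-10) ~ 4.5e-5: near-empty draws
        cov = toy_cov(10)
        prev = random_network(cov.roster, 0.4, rng)
        theta = pd.Series({"edges": -10.0})
        sims = sample_transition(prev, theta, theta, ModelSpec(("edges",)), cov, 10, seed=0)
        assert np.mean([s.density for s in sims]) < 0.01
        # ...and from an empty start, formation alone keeps it near-empty
        empty = from_dyad_vector(np.zeros(45, dtype=int), cov.roster)
        sims = sample_transition(empty, theta, theta, ModelSpec(("edges",)), cov, 10, seed=1)
        assert np.mean([s.density for s in sims]) < 0.01

    def test_strong_persistence_keeps_day_two_close_to_day_one(self, rng):
        from cownet.prediction import graph_correlation

        cov = toy_cov(40, seed=5)
        prev = random_network(cov.roster, 0.3, rng)
        theta_f = pd.Series({"edges": -10.0})
        theta_p = pd.Series({"edges": 10.0})
        sims = sample_transition(prev, theta_f, theta_p, ModelSpec(("edges",)), cov, 3, seed=1)
        for s in sims:
            assert graph_correlation(prev, s) > 0.95

    def test_dyad_independent_frequencies_match_logistic_probabilities(self, rng):
        cov = toy_cov(10, seed=2)
        prev = random_network(cov.roster, 0.4, rng)
        spec = ModelSpec.m1()
        theta_f = pd.Series(
            {"edges": -1.5, "parity_2": 0.2, "parity_3plus": 0.3, "parity_match": 0.2,
             "kinship": 1.0, "kindergarten": 0.5}
        )
        theta_p = pd.Series(
            {"edges": 0.5, "parity_2": 0.1, "parity_3plus": 0.1, "parity_match": 0.1,
             "kinship": 0.8, "kindergarten": 0.4}
        )
        n_samp = 2000
        sims = sample_transition(prev, theta_f, theta_p, spec, cov, n_samp, seed=7)
        iu, ju = dyads(10)
        freq = np.mean([s.adjacency[iu, ju] for s in sims], axis=0)
        from cownet.stergm import _linear_predictor

        eta_f, _ = _linear_predictor(theta_f, spec, cov)
        eta_p, _ = _linear_predictor(theta_p, spec, cov)
        p_prev = prev.adjacency[iu, ju]
        eta = np.where(p_prev == 1, eta_p[iu, ju], eta_f[iu, ju])
        p_exact = 1 / (1 + np.exp(-eta))
        se = np.sqrt(p_exact * (1 - p_exact) / n_samp)
        assert np.all(np.abs(freq - p_exact) <= 3 * se + 1e-12)

    def test_m2_sampler_matches_exhaustive_enumeration(self, rng):
        """Formation-phase M2 frequencies vs the 2^k exact distribution.

        Four nodes with two prior ties leave 4 free dyads (16 states), small
        enough that Monte-Carlo noise at 4,000 samples sits well under the
        0.05 total-variation bound.
        """
        n = 4
        cov = toy_cov(n, seed=4)
        prev = from_dyad_vector(np.array([1, 1, 0, 0, 0, 0]), cov.roster)
        spec = ModelSpec(("edges", "triangles"))
        theta = pd.Series({"edges": -0.5, "triangles": 0.4})
        exact = enumerate_phase_distribution(prev, theta.to_numpy(), spec, cov, "formation")
        theta_p = pd.Series({"edges": 10.0, "triangles": 0.0})  # keep all ties
        n_samp = 4000
        sims = sample_transition(prev, theta, theta_p, spec, cov, n_samp, seed=11)
        iu, ju = dyads(n)
        free = np.flatnonzero(prev.adjacency[iu, ju] == 0)
        counts: dict = {}
        for s in sims:
            bits = tuple(s.adjacency[iu, ju][free])
            counts[bits] = counts.get(bits, 0) + 1
        tv = 0.5 * sum(
            abs(counts.get(bits, 0) / n_samp - p) for bits, p in exact.items()
        )
        assert tv < 0.05

    def test_invalid_sample_count_rejected(self, rng):
        cov = toy_cov(5)
        prev = random_network(cov.roster, 0.5, rng)
        with pytest.raises(ValueError):
            sample_transition(prev, pd.Series({"edges": 0.0}), pd.Series({"edges": 0.0}),
                              ModelSpec(("edges",)), cov, 0)

    def test_missing_coefficient_rejected(self, rng):
        cov = toy_cov(5)
        prev = random_network(cov.roster, 0.5, rng)
        with pytest.raises(ModelSpecError):
            sample_transition(prev, pd.Series({"edges": 0.0}), pd.Series({"edges": 0.0}),
                              ModelSpec(("edges", "kinship")), cov, 1)


class TestSimulateFromFit:
    def test_nonconverged_fit_requires_override(self, rng):
        cov = toy_cov(5)
        prev = from_dyad_vector(np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0]), cov.roster)
        empty = from_dyad_vector(np.zeros(10, dtype=int), cov.roster)
        fit = fit_mple([decompose_transition(prev, empty)], ModelSpec(("edges",)), cov)
        assert not fit.converged
        with pytest.raises(FitError):
            simulate_transition(prev, fit, ModelSpec(("edges",)), cov, 2)


@pytest.fixture(scope="module")
def m1_fit_setup():
    from cownet.synthetic import SimulationConfig, generate_herd, generate_network_series
    from cownet.covariates import build_dyad_covariates

    herd, ped = generate_herd(40, 6, seed=9)
    cov = build_dyad_covariates(ped, herd, herd["cow_id"])
    cfg = SimulationConfig(n_cows=40, n_days=6, seed=13)
    series = generate_network_series(cov, cfg)
    transitions = [decompose_transition(a, b) for a, b in zip(series[:-1], series[1:])]
    fit = fit_mple(transitions, ModelSpec.m1(), cov)
    return fit, series, cov


class TestDegeneracy:
    def test_well_specified_m1_not_flagged(self, m1_fit_setup):
        fit, series, cov = m1_fit_setup
        assert fit.converged
        report = assess_degeneracy(fit, series[-2], ModelSpec.m1(), cov, seed=3)
        assert not report["degenerate"], report["flags"]

    def test_large_triangle_coefficient_flags_near_complete_graph(self, rng):
        import dataclasses

        cov = toy_cov(30, seed=6)
        prev = random_network(cov.roster, 0.2, rng)
        nxt = random_network(cov.roster, 0.2, np.random.default_rng(1))
        spec = ModelSpec(("edges", "triangles"))
        fit = fit_mple([decompose_transition(prev, nxt)], spec, cov)
        boosted = pd.Series({"edges": 1.0, "triangles": 5.0})
        fit = dataclasses.replace(
            fit,
            formation=dataclasses.replace(fit.formation, coefs=boosted, se=boosted * 0 + 0.1),
            persistence=dataclasses.replace(fit.persistence, coefs=boosted, se=boosted * 0 + 0.1),
        )
        report = assess_degeneracy(fit, prev, spec, cov, seed=5, n_sim=30)
        assert report["degenerate"]
        assert any("near-uniform" in f or "off by" in f for f in report["flags"])

    def test_nonfinite_se_flagged_without_simulation(self, rng):
        cov = toy_cov(5)
        prev = from_dyad_vector(np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0]), cov.roster)
        empty = from_dyad_vector(np.zeros(10, dtype=int), cov.roster)
        fit = fit_mple([decompose_transition(prev, empty)], ModelSpec(("edges",)), cov)
        report = assess_degeneracy(fit, prev, ModelSpec(("edges",)), cov)
        assert report["degenerate"]
        assert "non-finite" in report["flags"][0]
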