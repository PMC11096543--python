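import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_2samp

from conftest import make_chain_network
from polyflux.errors import InfeasibleError
from polyflux.network import stoichiometric_matrix
from polyflux.polytope import FluxPolytope, build_polytope
from polyflux.rates import ExchangeRateSet
from polyflux.sampling import (FluxPosterior, hit_and_run, loop_free,
                               mc_standard_error, remove_loops,
                               sample_posterior, summarize_posterior)


def simplex_polytope():
    return FluxPolytope(A_eq=[[1.0, 1.0, 1.0]], b_eq=[1.0],
                        lb=[0.0] * 3, ub=[1.0] * 3, rxn_ids=["a", "b", "c"])


def segment_polytope():
    """1-D segment v1 in [0, 2] embedded via v1 + v2 = 2."""
    return FluxPolytope(A_eq=[[1.0, 1.0]], b_eq=[2.0],
                        lb=[0.0, 0.0], ub=[2.0, 2.0], rxn_ids=["x", "y"])


class TestBuildPolytope:
    def test_clamped_chain_is_a_point(self, chain_net):
        p = build_polytope(chain_net)
        draws = hit_and_run(p, 5, seed=0)
        np.testing.assert_allclose(draws, np.tile([-1, 1, 1, 1], (5, 1)),
                                   atol=1e-9)

    def test_point_polytope_warns(self, chain_net):
        p = build_polytope(chain_net)
        with pytest.warns(UserWarning, match="single point"):
            hit_and_run(p, 3, seed=0)

    def test_zero_width_windows_on_noisy_rates_infeasible_with_k_prime(
            self, core_net, noiseless_measurements):
        mu, rs = noiseless_measurements
        # perturb rates jointly-inconsistently, then demand exact reproduction
        bad = {m: q * (1.2 if q > 0 else 1.0) for m, q in rs.rates.items()}
        bad_rs = ExchangeRateSet(sample_id="m1", condition="B6", rates=bad,
                                 sem={m: abs(q) * 0.05 for m, q in bad.items()})
        with pytest.raises(InfeasibleError) as err:
            build_polytope(core_net, rates=bad_rs, mu=mu, k=0.0)
        assert err.value.detail is not None and err.value.detail > 0

    def test_ground_truth_inside_noiseless_polytope(
            self, core_net, noiseless_scenario, noiseless_measurements):
        mu, rs = noiseless_measurements
        p = build_polytope(core_net, rates=rs, mu=mu)
        assert p.contains(noiseless_scenario.v_star)

    def test_unmeasured_exchanges_keep_default_bounds(self, core_net,
                                                      noiseless_measurements):
        mu, rs = noiseless_measurements
        p = build_polytope(core_net, rates=rs, mu=mu)
        j = p.reaction_index("EX_nh4")
        assert (p.lb[j], p.ub[j]) == (-1000.0, 1000.0)


class TestHitAndRun:
    def test_segment_mean(self):
        draws = hit_and_run(segment_polytope(), 4000, seed=1, burn_in=200,
                            thin=2)
        x = draws[:, 0]
        assert abs(x.mean() - 1.0) <= 3 * mc_standard_error(x)

    def test_simplex_matches_dirichlet_moments(self):
        draws = hit_and_run(simplex_polytope(), 8000, seed=2, burn_in=1000,
                            thin=5)
        for j in range(3):
            x = draws[:, j]
            assert abs(x.mean() - 1 / 3) <= 3 * mc_standard_error(x)
            se_var = mc_standard_error((x - x.mean()) ** 2)
            assert abs(x.var() - 1 / 18) <= 3 * se_var

    def test_equality_constraints_hold_exactly(self):
        draws = hit_and_run(simplex_polytope(), 500, seed=3, burn_in=100)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-10)
        assert draws.min() >= -1e-10

    def test_deterministic_given_seed(self):
        a = hit_and_run(simplex_polytope(), 200, seed=7, burn_in=50)
        b = hit_and_run(simplex_polytope(), 200, seed=7, burn_in=50)
        np.testing.assert_array_equal(a, b)
        c = hit_and_run(simplex_polytope(), 200, seed=8, burn_in=50)
        assert not np.array_equal(a, c)


def _graph_cycle_oracle(net, v, tol=1e-6):
    """Independent loop check for unimolecular networks: a thermodynamic loop
    exists iff the directed graph of active internal unit conversions
    (metabolite -> metabolite along the flux direction) contains a cycle."""
    import networkx as nx

    G = nx.DiGraph()
    for j, rxn in enumerate(net.reactions):
        if rxn.is_exchange or rxn.id == net.biomass_reaction_id or abs(v[j]) < tol:
            continue
        subs = [m for m, c in rxn.stoichiometry.items() if c * np.sign(v[j]) < 0]
        prods = [m for m, c in rxn.stoichiometry.items() if c * np.sign(v[j]) > 0]
        for s in subs:
            for t in prods:
                G.add_edge(s, t)
    try:
        nx.find_cycle(G)
        return False  # cycle found -> not loop-free
    except nx.NetworkXNoCycle:
        return True


class TestLoopLaw:
    def chain_flux(self, cycle_net, circulation=0.0):
        _, _, rxn_ids = stoichiometric_matrix(cycle_net)
        v = np.zeros(len(rxn_ids))
        for r, val in [("EX_A", -1), ("R1", 1), ("EX_B", 1)]:
            v[rxn_ids.index(r)] = val
        for r in ("C1", "C2", "C3"):
            v[rxn_ids.index(r)] = circulation
        return v, rxn_ids

    def test_pure_chain_is_loop_free(self, cycle_net):
        v, _ = self.chain_flux(cycle_net)
        assert loop_free(cycle_net, v)

    def test_superimposed_circulation_detected_and_repaired(self, cycle_net):
        v, rxn_ids = self.chain_flux(cycle_net, circulation=1.0)
        assert not loop_free(cycle_net, v)
        w = remove_loops(cycle_net, v)
        expected, _ = self.chain_flux(cycle_net, circulation=0.0)
        np.testing.assert_allclose(w, expected, atol=1e-9)

    def test_reverse_circulation_also_detected(self, cycle_net):
        v, _ = self.chain_flux(cycle_net, circulation=-2.5)
        assert not loop_free(cycle_net, v)

    def test_agrees_with_graph_cycle_oracle_on_random_fluxes(self, cycle_net):
        rng = np.random.default_rng(11)
        checked_loopy = checked_clean = 0
        for _ in range(40):
            chain_coeff = rng.normal(scale=2.0)
            cycle_coeff = rng.choice([0.0, rng.normal(scale=2.0)])
            v, _ = self.chain_flux(cycle_net)
            v = v * chain_coeff
            for r in ("C1", "C2", "C3"):
                v[[i for i, x in enumerate(cycle_net.reactions)
                   if x.id == r][0]] += cycle_coeff
            expected = _graph_cycle_oracle(cycle_net, v)
            assert loop_free(cycle_net, v) == expected
            checked_loopy += not expected
            checked_clean += expected
        assert checked_loopy > 0 and checked_clean > 0

    def test_core_ground_truth_is_loop_free(self, noiseless_scenario):
        assert loop_free(noiseless_scenario.network, noiseless_scenario.v_star)


class TestBiasedPosterior:
    def test_beta_zero_reduces_to_uniform(self):
        p = segment_polytope()
        post = sample_posterior(p, ras=None, beta=0.0, n=3000, seed=4,
                                burn_in=200, thin=2)
        x = post.draws[:, 0]
        assert abs(x.mean() - 1.0) <= 3 * mc_standard_error(x)
        assert post.metadata["acceptance_rate"] == 1.0

    def test_two_branch_bias_matches_quadrature(self):
        """Unit input split over branches scored (1, 0): the posterior mean of
        branch 1 must match 1-D numerical integration of the target."""
        p = FluxPolytope(A_eq=[[1.0, 1.0]], b_eq=[1.0], lb=[0.0, 0.0],
                         ub=[1.0, 1.0], rxn_ids=["b1", "b2"])
        beta, vscale = 10.0, 1.0
        post = sample_posterior(p, ras={"b1": 1.0, "b2": 0.0}, beta=beta,
                                vscale=vscale, n=6000, seed=5, burn_in=500,
                                thin=3)
        dens = lambda t: np.exp(-beta * ((t - 1.0) ** 2 + (1.0 - t) ** 2))
        z, _ = quad(dens, 0, 1)
        target_mean, _ = quad(lambda t: t * dens(t) / z, 0, 1)
        x = post.draws[:, 0]
        assert x.mean() > post.draws[:, 1].mean()
        assert abs(x.mean() - target_mean) <= 4 * mc_standard_error(x)

    def test_equal_scores_indistinguishable_from_uniform(self):
        """When every flux exceeds the normalization scale, the capped bias
        term is the same constant for all states and cancels in Metropolis:
        per-reaction KS tests vs the beta=0 chain, Benjamini-Hochberg at
        alpha=0.01."""
        p = FluxPolytope(A_eq=[[1.0, 1.0]], b_eq=[3.0], lb=[1.0, 1.0],
                         ub=[2.0, 2.0], rxn_ids=["a", "b"])
        flat = sample_posterior(p, ras={"a": 0.6, "b": 0.6}, beta=5.0,
                                vscale=0.5, n=2500, seed=6, burn_in=300,
                                thin=3)
        unif = sample_posterior(p, ras=None, beta=0.0, n=2500, seed=60,
                                burn_in=300, thin=3)
        assert flat.metadata["acceptance_rate"] == 1.0
        pvals = sorted(ks_2samp(flat.draws[:, j], unif.draws[:, j]).pvalue
                       for j in range(2))
        m = len(pvals)
        assert all(pv >= 0.01 * (i + 1) / m for i, pv in enumerate(pvals))

    def test_rejection_on_always_loopy_polytope_fails_loudly(self, cycle_net):
        """On a polytope whose interior consists entirely of loop-carrying
        states, rejection cannot retain draws; the sampler reports the
        rejection count instead of looping forever."""
        p = build_polytope(cycle_net)
        with pytest.raises(RuntimeError, match="loop rejections"):
            sample_posterior(p, ras=None, beta=0.0, n=20, seed=9,
                             burn_in=50, thin=2)

    def test_retained_draws_on_loop_free_network_all_pass(
            self, core_net, noiseless_measurements):
        mu, rs = noiseless_measurements
        p = build_polytope(core_net, rates=rs, mu=mu)
        post = sample_posterior(p, ras=None, beta=0.0, n=40, seed=9,
                                burn_in=200, thin=3)
        for v in post.draws:
            assert loop_free(core_net, v)

    def test_deterministic_given_seed(self):
        p = simplex_polytope()
        kw = dict(ras={"a": 1.0, "b": 0.0, "c": 0.5}, beta=2.0, n=100,
                  burn_in=50, thin=2)
        a = sample_posterior(p, seed=13, **kw)
        b = sample_posterior(p, seed=13, **kw)
        np.testing.assert_array_equal(a.draws, b.draws)


class TestSummaries:
    def test_single_draw_summary(self):
        fp = FluxPosterior("m1", "B6", np.array([[1.0, -2.0]]), ["r1", "r2"])
        s = summarize_posterior(fp)
        assert s.loc["r1", "mean"] == 1.0
        assert s.loc["r2", "sd"] == 0.0

    def test_point_polytope_quantiles_collapse(self, chain_net):
        p = build_polytope(chain_net)
        with pytest.warns(UserWarning):
            post = sample_posterior(p, n=10, seed=0, burn_in=10, thin=1)
        s = summarize_posterior(post)
        assert (s["q0.05"] == s["q0.95"]).all()

    def test_simplex_summary_matches_dirichlet(self):
        draws = hit_and_run(simplex_polytope(), 6000, seed=21, burn_in=400,
                            thin=3)
        fp = FluxPosterior("m1", "B6", draws, ["a", "b", "c"])
        s = summarize_posterior(fp)
        assert s["mean"].to_numpy() == pytest.approx([1 / 3] * 3, abs=0.02)
        assert s["sd"].to_numpy() == pytest.approx([np.sqrt(1 / 18)] * 3,
                                                   abs=0.02)
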