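from itertools import combinations
from math import comb

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from polyflux.compare import (compare_conditions, exact_wilcoxon,
                              fraction_reactions_higher, oxppp_fraction,
                              pyruvate_lactate_fraction)
from polyflux.errors import DegenerateInputError, ValidationError
from polyflux.network import stoichiometric_matrix
from polyflux.sampling import FluxPosterior


def posterior(draws, rxn_ids, sid="m1", cond="B6"):
    return FluxPosterior(sid, cond, np.asarray(draws, float), rxn_ids)


class TestFractionHigher:
    def test_identical_cohorts_give_zero(self):
        a = [posterior([[1.0, 2.0]], ["r1", "r2"])]
        assert fraction_reactions_higher(a, a) == 0.0

    def test_uniform_doubling_gives_one(self):
        ids = ["r1", "r2", "r3"]
        a = [posterior([[1.0, -2.0, 0.5]], ids)]
        b = [posterior([[2.0, -4.0, 1.0]], ids)]
        assert fraction_reactions_higher(a, b) == 1.0

    def test_zero_flux_reactions_excluded_from_denominator(self):
        ids = ["r1", "r2"]
        a = [posterior([[1.0, 0.0]], ids)]
        b = [posterior([[2.0, 0.0]], ids)]
        assert fraction_reactions_higher(a, b) == 1.0

    def test_absolute_values_ignore_direction_convention(self):
        ids = ["r1"]
        a = [posterior([[-1.0]], ids)]
        b = [posterior([[-2.0]], ids)]  # larger magnitude, negative sign
        assert fraction_reactions_higher(a, b) == 1.0

    def test_mismatched_reaction_sets_rejected(self):
        a = [posterior([[1.0]], ["r1"])]
        b = [posterior([[1.0]], ["r2"])]
        with pytest.raises(ValidationError):
            fraction_reactions_higher(a, b)

    def test_complementarity_without_ties(self):
        rng = np.random.default_rng(3)
        ids = [f"r{i}" for i in range(20)]
        a = [posterior(rng.normal(1, 0.1, (5, 20)), ids)]
        b = [posterior(rng.normal(1, 0.1, (5, 20)), ids)]
        assert fraction_reactions_higher(a, b) + \
            fraction_reactions_higher(b, a) == pytest.approx(1.0)


class TestDerivedFractions:
    def v_star_split(self, core_net, lactate_share):
        """Ground-truth-style vector splitting pyruvate production between
        lactate and everything else in a chosen proportion (only the pyr/lac
        entries matter for the statistic)."""
        _, _, rxn_ids = stoichiometric_matrix(core_net)
        v = np.zeros(len(rxn_ids))
        idx = {r: i for i, r in enumerate(rxn_ids)}
        v[idx["PYK"]] = 3.0  # sole pyruvate producer here
        v[idx["LDH"]] = 3.0 * lactate_share
        v[idx["PDH"]] = 3.0 * (1 - lactate_share)
        v[idx["EX_glc"]] = -1.5
        v[idx["EX_lac"]] = 3.0 * lactate_share
        return v, rxn_ids

    def test_two_to_one_split_gives_two_thirds(self, core_net):
        v, ids = self.v_star_split(core_net, 2 / 3)
        fp = posterior([v], ids)
        assert pyruvate_lactate_fraction(fp, core_net) == pytest.approx(2 / 3)

    def test_all_pyruvate_to_lactate_gives_one(self, core_net):
        v, ids = self.v_star_split(core_net, 1.0)
        assert pyruvate_lactate_fraction(posterior([v], ids), core_net) == \
            pytest.approx(1.0)

    def test_lactate_closed_gives_zero(self, core_net):
        v, ids = self.v_star_split(core_net, 0.0)
        assert pyruvate_lactate_fraction(posterior([v], ids), core_net) == 0.0

    def test_no_pyruvate_production_is_degenerate(self, core_net):
        _, _, ids = stoichiometric_matrix(core_net)
        with pytest.raises(DegenerateInputError):
            pyruvate_lactate_fraction(posterior([np.zeros(len(ids))], ids),
                                      core_net)

    def test_oxppp_ten_percent_of_glucose(self, core_net):
        _, _, ids = stoichiometric_matrix(core_net)
        v = np.zeros(len(ids))
        idx = {r: i for i, r in enumerate(ids)}
        v[idx["EX_glc"]] = -2.0
        v[idx["G6PD"]] = 0.2
        assert oxppp_fraction(posterior([v], ids), core_net) == \
            pytest.approx(0.10)

    def test_oxppp_closed_gives_zero(self, core_net):
        _, _, ids = stoichiometric_matrix(core_net)
        v = np.zeros(len(ids))
        v[ids.index("EX_glc")] = -2.0
        assert oxppp_fraction(posterior([v], ids), core_net) == 0.0

    def test_oxppp_invariant_to_uniform_flux_rescaling(self, core_net):
        _, _, ids = stoichiometric_matrix(core_net)
        v = np.zeros(len(ids))
        v[ids.index("EX_glc")] = -1.0
        v[ids.index("G6PD")] = 0.15
        f1 = oxppp_fraction(posterior([v], ids), core_net)
        f2 = oxppp_fraction(posterior([v * 7.5], ids), core_net)
        assert f1 == pytest.approx(f2)

    def test_zero_glucose_uptake_is_degenerate(self, core_net):
        _, _, ids = stoichiometric_matrix(core_net)
        v = np.zeros(len(ids))
        v[ids.index("G6PD")] = 0.1
        with pytest.raises(DegenerateInputError):
            oxppp_fraction(posterior([v], ids), core_net)


def enumeration_p(a, b):
    """Direct re-enumeration (kept deliberately naive) for cross-checking."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    obs = ranks[: len(a)].sum()
    lo = hi = 0
    for idx in combinations(range(len(pooled)), len(a)):
        t = ranks[list(idx)].sum()
        lo += t <= obs + 1e-9
        hi += t >= obs - 1e-9
    return min(1.0, 2 * min(lo, hi) / comb(len(pooled), len(a)))


class TestExactWilcoxon:
    def test_complete_separation_four_vs_four(self):
        _, p = exact_wilcoxon([1, 2, 3, 4], [5, 6, 7, 8])
        assert p == pytest.approx(2 / 70)

    def test_one_step_from_extreme(self):
        # rank sum one step above the minimum: p = 4/70
        _, p = exact_wilcoxon([1, 2, 3, 5], [4, 6, 7, 8])
        assert p == pytest.approx(4 / 70)

    def test_all_tied_gives_one(self):
        _, p = exact_wilcoxon([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            exact_wilcoxon([], [1.0])

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_matches_scipy_exact_distribution(self, n):
        """Tie-free samples: agree with scipy's exact Mann-Whitney p-value
        for every tested configuration with nA = nB <= 5."""
        rng = np.random.default_rng(n)
        for _ in range(20):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            _, p = exact_wilcoxon(a, b)
            p_scipy = mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue
            assert p == pytest.approx(p_scipy, abs=1e-12)

    def test_midrank_ties_match_naive_enumeration(self):
        a = [1.0, 2.0, 2.0, 5.0]
        b = [2.0, 3.0, 4.0]
        _, p = exact_wilcoxon(a, b)
        assert p == pytest.approx(enumeration_p(np.array(a), np.array(b)))


class TestCompareConditions:
    def test_end_to_end_summary_structure(self, core_net):
        _, _, ids = stoichiometric_matrix(core_net)
        idx = {r: i for i, r in enumerate(ids)}
        rng = np.random.default_rng(0)

        def cohort(scale, cond):
            posts = []
            for i in range(4):
                v = np.zeros(len(ids))
                v[idx["PYK"]] = 3.0 * scale
                v[idx["LDH"]] = 2.0 * scale
                v[idx["PDH"]] = 1.0 * scale
                v[idx["EX_glc"]] = -1.5 * scale
                v[idx["EX_lac"]] = 2.0 * scale
                v[idx["G6PD"]] = 0.15 * scale
                draws = v[None, :] * (1 + 0.01 * rng.normal(size=(50, 1)))
                posts.append(posterior(draws, ids, sid=f"{cond}_m{i}",
                                       cond=cond))
            return posts

        res = compare_conditions(cohort(1.0, "B6"), cohort(1.3, "TC"), core_net)
        assert res.fraction_higher == 1.0
        assert res.lactate_fraction_a[0] == pytest.approx(2 / 3, abs=0.01)
        assert 0 < res.lactate_p <= 1.0
        summary = res.summary()
        assert set(summary) == {"fraction_reactions_higher_in_b",
                                "pyruvate_to_lactate_fraction",
                                "oxppp_fraction"}
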