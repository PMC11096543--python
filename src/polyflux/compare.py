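"""Condition-level comparison of posterior fluxes.

Cohort statistics follow the per-animal design: each mouse contributes one
posterior-mean flux vector; derived quantities (share of pyruvate excreted
as lactate, share of glucose entering the oxidative PPP) are computed per
mouse and compared between cohorts with an exact Wilcoxon rank-sum test
(enumeration over all group assignments, midranks for ties).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateInputError, ValidationError
from .network import MetabolicNetwork
from .sampling import FluxPosterior

ZERO_FLUX_TOL = 1e-9


def _cohort_abs_means(posts: list[FluxPosterior]) -> np.ndarray:
    """Cohort mean of |per-mouse posterior mean| per reaction."""
    return np.mean([np.abs(fp.mean()) for fp in posts], axis=0)


def fraction_reactions_higher(posts_a: list[FluxPosterior],
                              posts_b: list[FluxPosterior]) -> float:
    """Share of reactions whose cohort-mean |flux| is strictly higher in B.

    Reactions carrying (numerically) zero flux in both cohorts are excluded
    from the denominator.  Both cohorts must share the same reaction index.
    """
    if not posts_a or not posts_b:
        raise ValidationError("both cohorts need at least one posterior")
    ids = posts_a[0].rxn_ids
    for fp in posts_a + posts_b:
        if fp.rxn_ids != ids:
            raise ValidationError("posterior reaction sets do not match")
    a = _cohort_abs_means(posts_a)
    b = _cohort_abs_means(posts_b)
    active = (a > ZERO_FLUX_TOL) | (b > ZERO_FLUX_TOL)
    if not active.any():
        raise DegenerateInputError("all reactions carry zero flux in both cohorts")
    return float(np.sum(b[active] > a[active]) / np.sum(active))


def _flux_vector_fraction(v: np.ndarray, net: MetabolicNetwork, rxn_ids,
                          producers_of: str, consumed_into: str | None) -> float:
    """Generic metabolite partitioning on one flux vector.

    Denominator: total production flux of ``producers_of`` (sum over
    reactions of the positive part of coefficient*flux).  Numerator: its
    consumption by reactions that also produce ``consumed_into``.
    """
    idx = {r: i for i, r in enumerate(rxn_ids)}
    production = 0.0
    directed = 0.0
    for rxn in net.reactions:
        if rxn.is_exchange:
            continue
        coeff = rxn.stoichiometry.get(producers_of)
        if coeff is None:
            continue
        rate = coeff * v[idx[rxn.id]]
        if rate > 0:
            production += rate
        elif consumed_into is not None and rxn.stoichiometry.get(consumed_into, 0) != 0:
            made = rxn.stoichiometry[consumed_into] * v[idx[rxn.id]]
            if made > 0:
                directed += -rate
    if production <= ZERO_FLUX_TOL:
        raise DegenerateInputError(f"no production of {producers_of!r}")
    return directed / production


def pyruvate_lactate_fraction(post: FluxPosterior, net: MetabolicNetwork,
                              pyruvate: str = "pyr", lactate: str = "lac") -> float:
    """Fraction of produced pyruvate that is routed into lactate.

    Computed on the posterior-mean flux vector of one mouse; in [0, 1] up to
    numerical tolerance.
    """
    return _flux_vector_fraction(post.mean(), net, post.rxn_ids, pyruvate, lactate)


def oxppp_fraction(post: FluxPosterior, net: MetabolicNetwork,
                   entry_reaction: str = "G6PD",
                   glucose_exchange: str = "EX_glc") -> float:
    """Fraction of glucose uptake entering the oxidative PPP branch.

    Posterior-mean flux through the branch entry (G6PD) divided by the
    posterior-mean glucose uptake magnitude.
    """
    v = post.mean()
    idx = {r: i for i, r in enumerate(post.rxn_ids)}
    if entry_reaction not in idx:
        return 0.0
    uptake = abs(v[idx[glucose_exchange]])
    if uptake <= ZERO_FLUX_TOL:
        raise DegenerateInputError("zero glucose uptake")
    return float(abs(v[idx[entry_reaction]]) / uptake)


def exact_wilcoxon(a, b) -> tuple[float, float]:
    """Exact two-sided Wilcoxon rank-sum test for small samples.

    Pooled observations receive midranks; the null distribution of group A's
    rank sum is enumerated over all C(nA+nB, nA) assignments, and the
    two-sided p-value is min(1, 2*min(lower tail, upper tail)).  Returns
    (rank sum of A, p).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks for ties
    n_a, n = a.size, pooled.size
    observed = float(ranks[:n_a].sum())
    total = comb(n, n_a)
    lower = upper = 0
    for idx in combinations(range(n), n_a):
        t = ranks[list(idx)].sum()
        if t <= observed + 1e-9:
            lower += 1
        if t >= observed - 1e-9:
            upper += 1
    p = min(1.0, 2.0 * min(lower, upper) / total)
    return observed, p


@dataclass
class ConditionComparison:
    """Full two-cohort comparison: per-reaction table + derived statistics."""

    table: pd.DataFrame  # reaction_id, mean_a, mean_b, higher_in_b
    fraction_higher: float
    lactate_fraction_a: list[float]  # per mouse
    lactate_fraction_b: list[float]
    oxppp_fraction_a: list[float]
    oxppp_fraction_b: list[float]
    lactate_p: float
    oxppp_p: float

    def summary(self) -> dict:
        def ms(x):
            x = np.asarray(x, float)
            sem = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
            return {"mean": float(x.mean()), "sem": sem, "per_mouse": list(map(float, x))}

        return {
            "fraction_reactions_higher_in_b": self.fraction_higher,
            "pyruvate_to_lactate_fraction": {
                "a": ms(self.lactate_fraction_a), "b": ms(self.lactate_fraction_b),
                "wilcoxon_p": self.lactate_p,
            },
            "oxppp_fraction": {
                "a": ms(self.oxppp_fraction_a), "b": ms(self.oxppp_fraction_b),
                "wilcoxon_p": self.oxppp_p,
            },
        }


def compare_conditions(posts_a: list[FluxPosterior], posts_b: list[FluxPosterior],
                       net: MetabolicNetwork) -> ConditionComparison:
    frac = fraction_reactions_higher(posts_a, posts_b)
    a_means = _cohort_abs_means(posts_a)
    b_means = _cohort_abs_means(posts_b)
    table = pd.DataFrame({
        "reaction_id": posts_a[0].rxn_ids,
        "mean_a": a_means, "mean_b": b_means,
        "higher_in_b": b_means > a_means,
    })
    lac_a = [pyruvate_lactate_fraction(fp, net) for fp in posts_a]
    lac_b = [pyruvate_lactate_fraction(fp, net) for fp in posts_b]
    ox_a = [oxppp_fraction(fp, net) for fp in posts_a]
    ox_b = [oxppp_fraction(fp, net) for fp in posts_b]
    _, lac_p = exact_wilcoxon(lac_a, lac_b)
    _, ox_p = exact_wilcoxon(ox_a, ox_b)
    return ConditionComparison(
        table=table, fraction_higher=frac,
        lactate_fraction_a=lac_a, lactate_fraction_b=lac_b,
        oxppp_fraction_a=ox_a, oxppp_fraction_b=ox_b,
        lactate_p=lac_p, oxppp_p=ox_p,
    )
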