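"""Synthetic experiments generated from a known ground-truth flux vector.

Every pipeline stage can be tested end-to-end without animal data: a
loop-free feasible flux vector v* is drawn from the core network under
physiologically plausible exchange windows, and the culture measurements the
wet lab would produce (cell counts, supernatant concentrations, gene
expression) are fabricated from v* by closed-form forward simulation with
multiplicative measurement noise.  Zero noise makes the estimators'
closed-form inversion exact, which the tests exploit.

Defaults mirror the study conditions: medium with 25 mM glucose and 10 mM
glutamine, measurements on day 2 (48 h) and day 3 (72 h), n = 4 mice per
condition.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._lp import solve_lp
from .errors import InfeasibleError, ValidationError
from .expression import ExpressionProfile, parse_gpr
from .network import MetabolicNetwork, stoichiometric_matrix
from .polytope import FluxPolytope, build_polytope
from .rates import (DEFAULT_DRY_WEIGHT_PER_CELL, GrowthMeasurement,
                    SupernatantTimeCourse)
from .sampling import hit_and_run, loop_free, remove_loops, sample_posterior

log = logging.getLogger(__name__)

#: plausible specific-rate windows (mmol/gDW/hr, secretion positive) used to
#: draw ground-truth flux vectors on the core network
REALISTIC_WINDOWS = {
    "EX_glc": (-1.2, -0.8),
    "EX_gln": (-0.8, -0.25),
    "EX_ser": (-0.15, -0.02),
    "EX_o2": (-1.5, -0.1),
    "EX_lac": (0.5, 1000.0),
    "EX_glu": (0.05, 0.5),
    "EX_ala": (0.02, 0.3),
    "EX_asp": (0.01, 0.2),
    "EX_gly": (0.01, 0.2),
    "EX_co2": (0.0, 1000.0),
    "EX_nh4": (0.0, 1000.0),
    "BIOMASS": (0.02, 0.04),
    # internal capacity windows keeping the drawn state physiological:
    # oxPPP entry ~10-30% of glucose uptake, pyruvate oxidation a sizeable
    # share of pyruvate production, minor anaplerotic cycling
    "G6PD": (0.1, 0.3),
    "PDH": (0.15, 0.6),
    "PC": (0.0, 0.03),
    "ME2": (0.0, 0.03),
}

#: initial medium composition, mM (glucose and glutamine per the culture
#: protocol; amino acids at supplemented levels)
DEFAULT_MEDIUM = {
    "glc": 25.0, "gln": 10.0, "ser": 2.0,
    "lac": 0.0, "glu": 0.1, "ala": 0.1, "asp": 0.1, "gly": 0.1,
    # cumulative dissolved-oxygen delivery (mM equivalent): its decline
    # encodes the oxygen consumption rate the way extracellular flux
    # analysis reports OCR
    "o2": 15.0,
}

DEFAULT_TIMEPOINTS = (48.0, 72.0)  # hours: day 2 and day 3
#: supernatant is additionally sampled at culture start (defined medium baseline)
DEFAULT_CONC_TIMEPOINTS = (0.0, 48.0, 72.0)


def generate_ground_truth(net: MetabolicNetwork, seed,
                          windows: dict | None = None,
                          target_profile=None,
                          chain_steps: int = 2000) -> np.ndarray:
    """One loop-free feasible flux vector drawn from the constrained network.

    A short uniform hit-and-run chain (biased toward ``target_profile``
    activity scores when given) provides an interior point; any internal
    circulation is then removed by the loop-repair LP.  Deterministic given
    ``seed``.
    """
    if windows is None:
        windows = REALISTIC_WINDOWS if net.id.startswith("tcell_core") else {}
    windows = {k: v for k, v in windows.items()
               if k in {r.id for r in net.reactions}}
    p = build_polytope(net, extra_windows=windows)
    if target_profile is not None:
        post = sample_posterior(p, ras=target_profile, beta=5.0, n=1,
                                seed=seed, burn_in=chain_steps, thin=1)
        v = post.draws[-1]
    else:
        v = hit_and_run(p, n=1, seed=seed, burn_in=chain_steps, thin=1)[-1]
    v = remove_loops(net, v)
    if not loop_free(net, v):  # pragma: no cover - repair guarantees this
        raise RuntimeError("loop repair failed to produce a loop-free vector")
    return v


def project_to_polytope(p: FluxPolytope, v_target: np.ndarray) -> np.ndarray:
    """L1-nearest point of the polytope to ``v_target`` (LP projection)."""
    n = p.n_reactions
    eye = np.eye(n)
    A_ub = np.block([[eye, -eye], [-eye, -eye]])
    b_ub = np.concatenate([v_target, -v_target])
    A_eq = np.hstack([p.A_eq, np.zeros((p.A_eq.shape[0], n))])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    bounds = p.bounds_list() + [(0.0, None)] * n
    res = solve_lp(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=p.b_eq, bounds=bounds)
    return res.x[:n]


@dataclass
class SyntheticScenario:
    """Ground truth + noise model + seeds for one simulated condition."""

    network: MetabolicNetwork
    condition: str
    v_star: np.ndarray  # mmol/gDW/hr, loop-free, S v = 0
    mu_star: float  # per hour
    n_mice: int = 4
    medium: dict = field(default_factory=lambda: dict(DEFAULT_MEDIUM))
    timepoints: tuple = DEFAULT_TIMEPOINTS
    conc_timepoints: tuple = DEFAULT_CONC_TIMEPOINTS
    n0_cells: float = 7.5e5  # cells per culture at t = 0 (0.75e6/mL seeding)
    culture_volume: float = 1e-3  # liters
    dry_weight_per_cell: float = DEFAULT_DRY_WEIGHT_PER_CELL  # grams
    conc_noise_sd: float = 0.03  # relative, multiplicative
    count_noise_sd: float = 0.05
    expr_noise_sd: float = 0.3  # lognormal sigma
    expr_scale: float = 100.0
    informative_expression: bool = True
    master_seed: int = 0

    def validate(self) -> None:
        S, _, rxn_ids = stoichiometric_matrix(self.network)
        if np.max(np.abs(S @ self.v_star), initial=0.0) > 1e-9:
            raise ValidationError("ground-truth flux violates mass balance")
        if not loop_free(self.network, self.v_star):
            raise ValidationError("ground-truth flux contains a thermodynamic loop")
        j = rxn_ids.index(self.network.biomass_reaction_id)
        if abs(self.v_star[j] - self.mu_star) > 1e-9:
            raise ValidationError("biomass flux of v* does not equal mu*")

    def exchange_rate(self, met: str) -> float:
        ex = self.network.exchange_for_metabolite(met)
        if ex is None:
            raise ValidationError(f"no exchange for {met!r}")
        _, _, rxn_ids = stoichiometric_matrix(self.network)
        return float(self.v_star[rxn_ids.index(ex.id)])


def default_scenario(net: MetabolicNetwork | None = None, seed: int = 0,
                     condition: str = "B6", **overrides) -> SyntheticScenario:
    """Scenario with a freshly drawn ground truth on the core network."""
    if net is None:
        from .tcell_core import core_tcell_network

        net = core_tcell_network()
    v = generate_ground_truth(net, seed=[seed, 101])
    _, _, rxn_ids = stoichiometric_matrix(net)
    mu = float(v[rxn_ids.index(net.biomass_reaction_id)])
    sc = SyntheticScenario(network=net, condition=condition, v_star=v,
                           mu_star=mu, master_seed=seed, **overrides)
    sc.validate()
    return sc


def _distribute_through_gpr(tree, value: float, into: dict[str, float]) -> None:
    """Spread a reaction's activity level down its GPR tree.

    Every subunit of an AND complex carries the full level; isozymes under an
    OR share it equally.  Evaluating the rule with AND=min / OR=sum on the
    resulting gene levels then returns the reaction's level (exactly when the
    reaction has at least one exclusive gene, approximately otherwise), which
    is what makes the fabricated expression informative about the flux.
    """
    if tree.op == "gene":
        into[tree.gene] = into.get(tree.gene, 0.0) + value
    elif tree.op == "and":
        for child in tree.children:
            _distribute_through_gpr(child, value, into)
    else:  # or
        share = value / len(tree.children)
        for child in tree.children:
            _distribute_through_gpr(child, share, into)


def _gene_levels_from_flux(net: MetabolicNetwork, v: np.ndarray, rxn_ids,
                           informative: bool) -> dict[str, float]:
    """Noise-free per-gene levels encoding the capped normalized |flux|.

    Reaction levels are |v_r| normalized by the glucose-uptake magnitude and
    capped at 1 — the same functional the sampling bias compares scores
    against — so downstream activity scoring recovers a profile aligned with
    the ground truth.  With ``informative`` off, every reaction level is 1
    (expression carries no flux information).
    """
    idx = {r: i for i, r in enumerate(rxn_ids)}
    ex = net.exchange_for_metabolite("glc")
    if ex is not None and abs(v[idx[ex.id]]) > 1e-9:
        vscale = abs(float(v[idx[ex.id]]))
    else:
        vscale = float(np.max(np.abs(v), initial=1.0))
    levels: dict[str, float] = {}
    for rxn in net.reactions:
        tree = parse_gpr(rxn.gpr)
        if tree is None:
            continue
        w = min(abs(float(v[idx[rxn.id]])) / vscale, 1.0) if informative else 1.0
        _distribute_through_gpr(tree, w, levels)
    return levels


@dataclass
class SimulatedExperiment:
    """Per-mouse fabricated measurements for one condition."""

    condition: str
    growth: list[GrowthMeasurement]
    supernatant: dict[str, list[SupernatantTimeCourse]]  # sample_id -> courses
    expression: list[ExpressionProfile]
    depleted: list[tuple[str, str]] = field(default_factory=list)  # (sample, met)


def _auc_from_zero(n0: float, mu: float, t: float) -> float:
    if abs(mu) < 1e-12:
        return n0 * t
    return n0 * (np.exp(mu * t) - 1.0) / mu


def simulate_experiment(sc: SyntheticScenario) -> SimulatedExperiment:
    """Forward-simulate counts, supernatant concentrations and expression.

    Counts: N(t) = N0 exp(mu* t) with multiplicative lognormal noise.
    Concentrations: C(t) = C0 + q* AUC(0,t) w / V, floored at zero (with a
    depletion flag) and measured with multiplicative noise.  Expression:
    per-gene level proportional to the summed |v*| of the reactions whose
    GPR contains the gene (or flux-independent when
    ``informative_expression`` is off), with lognormal noise.  All
    randomness derives from the master seed; per-mouse streams are
    independent and reproducible.
    """
    sc.validate()
    net = sc.network
    _, _, rxn_ids = stoichiometric_matrix(net)
    gene_base = _gene_levels_from_flux(net, sc.v_star, rxn_ids,
                                       sc.informative_expression)

    growth, expression = [], []
    supernatant: dict[str, list[SupernatantTimeCourse]] = {}
    depleted = []
    cond_stream = zlib.crc32(sc.condition.encode()) % (2**31)
    for i in range(sc.n_mice):
        sid = f"{sc.condition}_m{i + 1}"
        rng = np.random.default_rng([sc.master_seed, 7001, cond_stream, i])
        counts = []
        for t in sc.timepoints:
            true_n = sc.n0_cells * np.exp(sc.mu_star * t)
            noise = np.exp(sc.count_noise_sd * rng.standard_normal()) \
                if sc.count_noise_sd else 1.0
            counts.append(float(true_n * noise))
        growth.append(GrowthMeasurement(
            sample_id=sid, condition=sc.condition,
            timepoints=list(sc.timepoints), counts=counts,
            culture_volume=sc.culture_volume,
            dry_weight_per_cell=sc.dry_weight_per_cell,
        ))
        courses = []
        for met, c0 in sorted(sc.medium.items()):
            q = sc.exchange_rate(met)
            concs = []
            for t in sc.conc_timepoints:
                auc = _auc_from_zero(sc.n0_cells, sc.mu_star, t)
                c_true = c0 + q * auc * sc.dry_weight_per_cell / sc.culture_volume
                if c_true < 0:
                    if (sid, met) not in depleted:
                        log.warning("%s: %s depleted before t=%g h; "
                                    "rate estimate will be biased", sid, met, t)
                        depleted.append((sid, met))
                    c_true = 0.0
                noise = np.exp(sc.conc_noise_sd * rng.standard_normal()) \
                    if sc.conc_noise_sd else 1.0
                concs.append(float(c_true * noise))
            courses.append(SupernatantTimeCourse(
                sample_id=sid, metabolite_id=met,
                timepoints=list(sc.conc_timepoints), concentrations=concs,
            ))
        supernatant[sid] = courses
        values = {}
        for gene in sorted(gene_base):
            noise = np.exp(sc.expr_noise_sd * rng.standard_normal()) \
                if sc.expr_noise_sd else 1.0
            values[gene] = float(sc.expr_scale * gene_base[gene] * noise)
        expression.append(ExpressionProfile(sample_id=sid, condition=sc.condition,
                                            values=values))
    return SimulatedExperiment(condition=sc.condition, growth=growth,
                               supernatant=supernatant, expression=expression,
                               depleted=depleted)


def two_condition_scenario(net: MetabolicNetwork | None, effect: dict,
                           seed: int = 0,
                           conditions: tuple[str, str] = ("B6", "TC"),
                           **overrides) -> tuple[SyntheticScenario, SyntheticScenario]:
    """Paired scenarios sharing a network and noise model.

    Condition B's ground truth is condition A's multiplied reaction-wise by
    ``effect`` (key ``"*"`` sets a default multiplier for unlisted
    reactions), then re-projected onto the flux polytope (L1-nearest
    feasible point) and loop-repaired, so it remains a valid ground truth.
    """
    sc_a = default_scenario(net, seed=seed, condition=conditions[0], **overrides)
    net = sc_a.network
    _, _, rxn_ids = stoichiometric_matrix(net)
    default_mult = float(effect.get("*", 1.0))
    mult = np.array([float(effect.get(r, default_mult)) for r in rxn_ids])
    v_b = sc_a.v_star * mult
    # pin growth at its intended value so the L1 re-projection cannot absorb
    # imbalances by silently inflating proliferation
    bio = net.biomass_reaction_id
    mu_target = float(v_b[rxn_ids.index(bio)])
    p = build_polytope(net, extra_windows={bio: (mu_target, mu_target)})
    v_b = project_to_polytope(p, v_b)
    v_b = remove_loops(net, v_b)
    if not loop_free(net, v_b):
        raise InfeasibleError("shifted ground truth could not be made loop-free")
    mu_b = float(v_b[rxn_ids.index(net.biomass_reaction_id)])
    if mu_b <= 0:
        raise InfeasibleError("shifted ground truth has non-positive growth")
    sc_b = replace(sc_a, condition=conditions[1], v_star=v_b, mu_star=mu_b)
    sc_b.validate()
    return sc_a, sc_b


# ---------------------------------------------------------------------------
# CSV export in the schemas consumed by the rates and expression stages


def write_experiment_csvs(exp: SimulatedExperiment, outdir) -> dict[str, str]:
    """Write counts.csv / concentrations.csv / expression.csv for one condition."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    rows = [
        {"sample_id": g.sample_id, "condition": g.condition, "time_h": t, "cells": c}
        for g in exp.growth for t, c in zip(g.timepoints, g.counts)
    ]
    paths["counts"] = os.path.join(outdir, f"counts_{exp.condition}.csv")
    pd.DataFrame(rows).to_csv(paths["counts"], index=False)

    rows = [
        {"sample_id": tc.sample_id, "metabolite": tc.metabolite_id,
         "time_h": t, "conc_mM": c}
        for courses in exp.supernatant.values() for tc in courses
        for t, c in zip(tc.timepoints, tc.concentrations)
    ]
    paths["concentrations"] = os.path.join(outdir, f"concentrations_{exp.condition}.csv")
    pd.DataFrame(rows).to_csv(paths["concentrations"], index=False)

    expr = pd.DataFrame({p.sample_id: p.values for p in exp.expression})
    expr.index.name = "gene"
    paths["expression"] = os.path.join(outdir, f"expression_{exp.condition}.csv")
    expr.to_csv(paths["expression"])
    return paths
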