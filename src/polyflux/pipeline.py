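"""Stage-wise pipeline: simulate -> CORE rates -> activity scores -> prune ->
posterior sampling -> condition comparison, with provenance capture.

Each stage reads only the previous stage's files, so ``run-all`` and the
manual stage sequence produce identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd

from . import __version__
from .compare import compare_conditions
from .config import RunConfig
from .context import polytope_for_network, prune_network
from .errors import InfeasibleError, PolyfluxError
from .expression import ExpressionProfile, read_expression_csv, score_network, write_scores_csv
from .network import MetabolicNetwork, load_network
from .polytope import build_polytope
from .rates import (ExchangeRateSet, aggregate_condition_rates,
                    estimate_sample_rates, read_concentration_csv,
                    read_growth_csv, read_rates_csv, write_rates_csv)
from .sampling import FluxPosterior, sample_posterior
from .synthetic import simulate_experiment, two_condition_scenario, write_experiment_csvs
from .tcell_core import core_tcell_network

log = logging.getLogger(__name__)


def _checksum(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: RunConfig, data_dir) -> list[str]:
    """Fabricate the two-condition synthetic experiment; returns written paths."""
    sc_a, sc_b = two_condition_scenario(
        None, effect=cfg.effect, seed=cfg.seed, conditions=cfg.conditions,
        n_mice=cfg.n_mice, culture_volume=cfg.culture_volume,
        dry_weight_per_cell=cfg.dry_weight_per_cell,
        conc_noise_sd=cfg.conc_noise_sd, count_noise_sd=cfg.count_noise_sd,
        expr_noise_sd=cfg.expr_noise_sd,
        informative_expression=cfg.informative_expression,
    )
    paths = []
    for sc in (sc_a, sc_b):
        exp = simulate_experiment(sc)
        paths.extend(write_experiment_csvs(exp, data_dir).values())
    return paths


def stage_corerates(cfg: RunConfig, data_dir, out_dir) -> list[str]:
    """Per-mouse growth rates and exchange rates, plus condition aggregates."""
    os.makedirs(out_dir, exist_ok=True)
    growth_rows, all_sets = [], []
    for cond in cfg.conditions:
        growth = read_growth_csv(os.path.join(data_dir, f"counts_{cond}.csv"),
                                 culture_volume=cfg.culture_volume,
                                 dry_weight_per_cell=cfg.dry_weight_per_cell)
        conc = read_concentration_csv(
            os.path.join(data_dir, f"concentrations_{cond}.csv"))
        sets = []
        for sid in sorted(growth):
            mu, rs = estimate_sample_rates(growth[sid], conc[sid])
            growth_rows.append({"sample_id": sid, "condition": cond, "mu_per_h": mu})
            sets.append(rs)
        agg = aggregate_condition_rates(sets)
        all_sets.extend(sets + [agg])
    rates_path = os.path.join(out_dir, "rates.csv")
    write_rates_csv(rates_path, all_sets)
    growth_path = os.path.join(out_dir, "growth.csv")
    pd.DataFrame(growth_rows).to_csv(growth_path, index=False)
    return [rates_path, growth_path]


def stage_ras(cfg: RunConfig, data_dir, out_dir, net: MetabolicNetwork) -> list[str]:
    """Reaction activity scores per sample from the expression tables."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for cond in cfg.conditions:
        expr = read_expression_csv(os.path.join(data_dir, f"expression_{cond}.csv"))
        for sid in expr.columns:
            profile = ExpressionProfile(sample_id=sid, condition=cond,
                                        values=expr[sid].to_dict())
            ras = score_network(net, profile)
            path = os.path.join(out_dir, f"ras_{sid}.csv")
            write_scores_csv(path, ras)
            paths.append(path)
    return paths


def _load_rate_sets(rates_path):
    per_sample: dict[str, ExchangeRateSet] = {}
    aggregates: dict[str, ExchangeRateSet] = {}
    for rs in read_rates_csv(rates_path):
        if rs.sample_id.endswith("_aggregate"):
            aggregates[rs.condition] = rs
        else:
            per_sample[rs.sample_id] = rs
    return per_sample, aggregates


def stage_prune(cfg: RunConfig, rates_path, growth_path, net: MetabolicNetwork,
                out_path) -> MetabolicNetwork:
    """Joint context model: keep reactions active under either condition's
    measured constraints; write the pruned network JSON."""
    _, aggregates = _load_rate_sets(rates_path)
    growth = pd.read_csv(growth_path)
    keep: set[str] = set()
    for cond, agg in aggregates.items():
        mu = float(growth.loc[growth["condition"] == cond, "mu_per_h"].mean())
        p = build_polytope(net, rates=agg, mu=mu, k=cfg.k, delta=cfg.delta)
        pruned = prune_network(net, p, tol=cfg.prune_tol)
        keep |= {r.id for r in pruned.reactions}
    if keep == {r.id for r in net.reactions}:
        merged = net
    else:
        import copy

        kept = [copy.deepcopy(r) for r in net.reactions if r.id in keep]
        used = {m for r in kept for m in r.stoichiometry}
        merged = MetabolicNetwork(
            metabolites=[copy.deepcopy(m) for m in net.metabolites if m.id in used],
            reactions=kept, biomass_reaction_id=net.biomass_reaction_id,
            compartments=list(net.compartments), id=net.id + "_pruned",
        )
        merged.validate()
    merged.save(out_path)
    return merged


def stage_sample(cfg: RunConfig, rates_path, growth_path, ras_dir,
                 net: MetabolicNetwork, out_dir) -> dict[str, list[FluxPosterior]]:
    """Per-mouse biased loop-free posterior sampling on the pruned network.

    Each mouse's polytope centers the exchange windows on that mouse's rates
    with the condition-level SEM (times k) as half-width.
    """
    from .expression import read_scores_csv

    os.makedirs(out_dir, exist_ok=True)
    per_sample, aggregates = _load_rate_sets(rates_path)
    growth = pd.read_csv(growth_path).set_index("sample_id")
    by_condition: dict[str, list[FluxPosterior]] = {c: [] for c in cfg.conditions}
    for i, sid in enumerate(sorted(per_sample)):
        rs = per_sample[sid]
        rs = ExchangeRateSet(sample_id=sid, condition=rs.condition, rates=rs.rates,
                             sem=aggregates[rs.condition].sem)
        mu = float(growth.loc[sid, "mu_per_h"])
        k_eff = cfg.k
        try:
            p = build_polytope(net, rates=rs, mu=mu, k=k_eff, delta=cfg.delta)
        except InfeasibleError as exc:
            # noisy per-animal rates can be jointly irreproducible at the
            # requested window width; fall back to the smallest feasible
            # widening (reported by the bisection) plus a 10% margin
            if exc.detail is None:
                raise
            k_eff = 1.1 * float(exc.detail)
            log.warning("%s: windows infeasible at k=%g; widened to k=%.3g",
                        sid, cfg.k, k_eff)
            p = build_polytope(net, rates=rs, mu=mu, k=k_eff, delta=cfg.delta)
        ras = read_scores_csv(os.path.join(ras_dir, f"ras_{sid}.csv"), sample_id=sid)
        post = sample_posterior(
            p, ras=ras, beta=cfg.beta, vscale=cfg.vscale, n=cfg.n_draws,
            seed=[cfg.seed, 9001, i], burn_in=cfg.burn_in, thin=cfg.thin,
            loop_tol=cfg.loop_tol, sample_id=sid, condition=rs.condition,
        )
        df = pd.DataFrame(post.draws, columns=post.rxn_ids)
        df.to_csv(os.path.join(out_dir, f"posterior_{sid}.csv"), index=False)
        meta = dict(post.metadata, sample_id=sid, condition=rs.condition,
                    seed=[cfg.seed, 9001, i], k_effective=k_eff)
        with open(os.path.join(out_dir, f"posterior_{sid}.meta.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True, default=float)
            fh.write("\n")
        by_condition[rs.condition].append(post)
    return by_condition


def load_posteriors(post_dir, condition: str) -> list[FluxPosterior]:
    posts = []
    for name in sorted(os.listdir(post_dir)):
        if name.startswith(f"posterior_{condition}_") and name.endswith(".csv"):
            df = pd.read_csv(os.path.join(post_dir, name))
            sid = name[len("posterior_"):-len(".csv")]
            posts.append(FluxPosterior(sample_id=sid, condition=condition,
                                       draws=df.to_numpy(), rxn_ids=list(df.columns)))
    return posts


def stage_compare(posts_by_condition, net: MetabolicNetwork, out_dir,
                  conditions) -> dict:
    os.makedirs(out_dir, exist_ok=True)
    a, b = conditions
    cmp_result = compare_conditions(posts_by_condition[a], posts_by_condition[b], net)
    cmp_result.table.to_csv(os.path.join(out_dir, "comparison.csv"), index=False)
    summary = cmp_result.summary()
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------


def run_pipeline(cfg: RunConfig, outdir, network_path=None) -> dict:
    """Execute all stages in order; returns the comparison summary.

    Writes a provenance record (config, seeds, versions, per-stage timings
    and artifact checksums) next to the outputs.  Any stage error aborts
    with the stage name attached.
    """
    os.makedirs(outdir, exist_ok=True)
    cfg.save(os.path.join(outdir, "config.json"))
    net = (load_network(network_path) if network_path else core_tcell_network())
    data_dir = os.path.join(outdir, "data")
    provenance = {"config": cfg.to_dict(), "versions": {
        "polyflux": __version__, "numpy": np.__version__,
    }, "stages": {}, "checksums": {}}
    artifacts = []
    stage_defs = [
        ("simulate", lambda: stage_simulate(cfg, data_dir)),
        ("corerates", lambda: stage_corerates(cfg, data_dir, outdir)),
        ("ras", lambda: stage_ras(cfg, data_dir, os.path.join(outdir, "ras"), net)),
    ]
    summary = None
    pruned = net
    try:
        for name, fn in stage_defs:
            t0 = time.perf_counter()
            paths = fn()
            provenance["stages"][name] = round(time.perf_counter() - t0, 3)
            artifacts.extend(paths or [])
        t0 = time.perf_counter()
        pruned_path = os.path.join(outdir, "pruned_network.json")
        pruned = stage_prune(cfg, os.path.join(outdir, "rates.csv"),
                             os.path.join(outdir, "growth.csv"), net, pruned_path)
        provenance["stages"]["prune"] = round(time.perf_counter() - t0, 3)
        artifacts.append(pruned_path)
        t0 = time.perf_counter()
        posts = stage_sample(cfg, os.path.join(outdir, "rates.csv"),
                             os.path.join(outdir, "growth.csv"),
                             os.path.join(outdir, "ras"), pruned,
                             os.path.join(outdir, "posteriors"))
        provenance["stages"]["sample"] = round(time.perf_counter() - t0, 3)
        t0 = time.perf_counter()
        summary = stage_compare(posts, pruned, outdir, cfg.conditions)
        provenance["stages"]["compare"] = round(time.perf_counter() - t0, 3)
        artifacts += [os.path.join(outdir, "comparison.csv"),
                      os.path.join(outdir, "summary.json")]
    except PolyfluxError as exc:
        stage = len(provenance["stages"])
        raise type(exc)(
            f"pipeline aborted at stage {stage + 1} "
            f"[code {exc.exit_code}]: {exc}"
        ) from exc
    for path in artifacts:
        provenance["checksums"][os.path.relpath(path, outdir)] = _checksum(path)
    post_dir = os.path.join(outdir, "posteriors")
    for name in sorted(os.listdir(post_dir)):
        provenance["checksums"][f"posteriors/{name}"] = _checksum(
            os.path.join(post_dir, name))
    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
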