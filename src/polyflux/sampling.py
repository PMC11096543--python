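"""Posterior flux sampling: hit-and-run over the polytope, loop-law screening,
and expression-biased Metropolis sampling.

The sampler works inside the null-space parameterization of the equality
constraints, so every proposal satisfies mass balance exactly by
construction; box bounds (including measurement windows) define the chord
limits of each hit-and-run step.  Thermodynamic feasibility is enforced by
rejection: a retained draw must contain no internal circulation (loop law /
second law), checked by a sign-constrained LP.  Transcriptome information
enters as a Metropolis bias toward reaction activity scores.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from ._lp import solve_lp
from .errors import DegenerateInputError, InfeasibleError
from .network import MetabolicNetwork, stoichiometric_matrix
from .polytope import FluxPolytope

log = logging.getLogger(__name__)

#: bounds narrower than this are treated as equality constraints
FIX_TOL = 1e-9


class AffineBasis:
    """Affine parameterization v = v0 + N t of the polytope's equality set.

    Degenerate box bounds (width below ``FIX_TOL``, e.g. point measurement
    windows from noiseless replicates) are folded into the equality system so
    the remaining coordinates span a full-dimensional region.
    """

    def __init__(self, p: FluxPolytope):
        n = p.n_reactions
        fixed = p.ub - p.lb <= FIX_TOL
        rows = [p.A_eq] if p.A_eq.size else []
        rhs = [p.b_eq] if p.b_eq.size else []
        if fixed.any():
            E = np.zeros((int(fixed.sum()), n))
            E[np.arange(int(fixed.sum())), np.flatnonzero(fixed)] = 1.0
            rows.append(E)
            rhs.append(0.5 * (p.lb[fixed] + p.ub[fixed]))
        A = np.vstack(rows) if rows else np.zeros((0, n))
        b = np.concatenate(rhs) if rhs else np.zeros(0)
        v0, *_ = np.linalg.lstsq(A, b, rcond=None) if A.size else (np.zeros(n),)
        if A.size and np.max(np.abs(A @ v0 - b), initial=0.0) > 1e-7:
            raise InfeasibleError("equality constraints are mutually inconsistent")
        self.v0 = v0
        self.N = null_space(A) if A.size else np.eye(n)
        self.dim = self.N.shape[1]
        self.free = ~fixed
        self.lb, self.ub = p.lb, p.ub
        self.polytope = p

    def point(self, t: np.ndarray) -> np.ndarray:
        return self.v0 + self.N @ t

    def chebyshev_center(self) -> np.ndarray:
        """t-coordinates of the largest inscribed ball's center (chain start)."""
        if self.dim == 0:
            return np.zeros(0)
        free = np.flatnonzero(self.free)
        Nf = self.N[free]
        norms = np.linalg.norm(Nf, axis=1)
        keep = norms > 1e-12
        Nf, norms, free = Nf[keep], norms[keep], free[keep]
        # rows: N_i t + r||N_i|| <= u_i - v0_i  and  -N_i t + r||N_i|| <= v0_i - l_i
        A_ub = np.vstack([np.column_stack([Nf, norms]),
                          np.column_stack([-Nf, norms])])
        b_ub = np.concatenate([self.ub[free] - self.v0[free],
                               self.v0[free] - self.lb[free]])
        c = np.zeros(self.dim + 1)
        c[-1] = -1.0
        r_cap = float(np.max(self.ub[free] - self.lb[free], initial=1.0))
        bounds = [(None, None)] * self.dim + [(0.0, r_cap)]
        res = solve_lp(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds)
        return res.x[:-1]


def _chord(x, w, lb, ub, eps=1e-12):
    """Intersection [s_min, s_max] of the line x + s*w with the box [lb, ub]."""
    s_min, s_max = -np.inf, np.inf
    pos = w > eps
    neg = w < -eps
    if pos.any():
        s_max = min(s_max, np.min((ub[pos] - x[pos]) / w[pos]))
        s_min = max(s_min, np.max((lb[pos] - x[pos]) / w[pos]))
    if neg.any():
        s_max = min(s_max, np.min((lb[neg] - x[neg]) / w[neg]))
        s_min = max(s_min, np.max((ub[neg] - x[neg]) / w[neg]))
    return s_min, s_max


def hit_and_run(p: FluxPolytope, n: int, seed, burn_in: int = 1000,
                thin: int = 10) -> np.ndarray:
    """Asymptotically uniform draws over ``p`` (draws x reactions).

    Deterministic given ``seed``.  A point polytope returns its single point
    (replicated) with a warning.
    """
    basis = AffineBasis(p)
    rng = np.random.default_rng(seed)
    if basis.dim == 0:
        warnings.warn("polytope is a single point; returning it for every draw")
        return np.tile(basis.point(np.zeros(0)), (n, 1))
    t = basis.chebyshev_center()
    x = basis.point(t)
    draws = np.empty((n, p.n_reactions))
    kept = 0
    step = 0
    total = burn_in + n * thin
    while kept < n:
        d = rng.standard_normal(basis.dim)
        d /= np.linalg.norm(d)
        w = basis.N @ d
        s_lo, s_hi = _chord(x, w, p.lb, p.ub)
        if s_hi > s_lo and np.isfinite(s_lo) and np.isfinite(s_hi):
            s = rng.uniform(s_lo, s_hi)
            t = t + s * d
            x = x + s * w
        step += 1
        if step % 1000 == 0:  # refresh against float drift
            x = basis.point(t)
        if step > burn_in and (step - burn_in) % thin == 0:
            draws[kept] = x
            kept += 1
        if step > 10 * total + 1000:
            raise RuntimeError("hit-and-run failed to advance")
    return draws


# ---------------------------------------------------------------------------
# loop law


def _loop_lp(net: MetabolicNetwork, v: np.ndarray, zero_tol: float = 1e-10):
    """Sign-constrained minimal-|flux| LP used for loop detection and repair.

    Exchange and biomass fluxes are pinned to their values in ``v``; every
    internal reaction r is confined to the interval between 0 and ``v_r``
    (so its sign cannot flip) and the total internal |flux| is minimized.
    The optimum equals sum(|v_internal|) exactly when ``v`` carries no
    internal circulation; otherwise the minimizer is ``v`` with all loops
    removed (the repaired vector).
    """
    S, _, rxn_ids = stoichiometric_matrix(net)
    pinned = np.array(
        [r.is_exchange or r.id == net.biomass_reaction_id for r in net.reactions]
    )
    c = np.zeros(len(rxn_ids))
    bounds = []
    for j, rid in enumerate(rxn_ids):
        if pinned[j]:
            bounds.append((v[j], v[j]))
        elif v[j] > zero_tol:
            bounds.append((0.0, v[j]))
            c[j] = 1.0
        elif v[j] < -zero_tol:
            bounds.append((v[j], 0.0))
            c[j] = -1.0
        else:
            bounds.append((0.0, 0.0))
    res = solve_lp(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds)
    internal_l1 = float(np.sum(np.abs(v[~pinned])))
    return res.x, float(res.fun), internal_l1


def loop_free(net: MetabolicNetwork, v, tol: float = 1e-6) -> bool:
    """True iff ``v`` contains no internal circulation (thermodynamic loop)."""
    v = np.asarray(v, dtype=float)
    _, opt, l1 = _loop_lp(net, v)
    return bool(l1 - opt <= tol * max(1.0, l1))

def remove_loops(net: MetabolicNetwork, v) -> np.ndarray:
    """Repaired flux vector: ``v`` with internal circulations subtracted.

    Exchange and biomass fluxes are unchanged; the result is loop-free and
    satisfies the same mass balance.
    """
    w, _, _ = _loop_lp(net, np.asarray(v, dtype=float))
    return w


# ---------------------------------------------------------------------------
# biased posterior sampling


@dataclass
class FluxPosterior:
    """Sampled flux vectors (draws x reactions) for one sample/condition."""

    sample_id: str
    condition: str
    draws: np.ndarray
    rxn_ids: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.draws = np.atleast_2d(np.asarray(self.draws, dtype=float))
        self._index = {r: i for i, r in enumerate(self.rxn_ids)}

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def reaction_mean(self, rxn_id: str) -> float:
        return float(self.draws[:, self._index[rxn_id]].mean())


def _bias_logdensity(v, scores, score_idx, beta, vscale):
    cap = np.minimum(np.abs(v[score_idx]) / vscale, 1.0)
    return -beta * float(np.sum((cap - scores) ** 2))


def sample_posterior(
    p: FluxPolytope,
    ras=None,
    beta: float = 5.0,
    vscale: float | None = None,
    n: int = 1000,
    seed=0,
    burn_in: int = 10000,
    thin: int = 100,
    loop_tol: float = 1e-6,
    sample_id: str = "sample",
    condition: str = "",
    acceptance_floor: float = 0.01,
) -> FluxPosterior:
    """Metropolis-within-hit-and-run draws from the biased flux posterior.

    Target density over ``p`` is proportional to
    ``exp(-beta * sum_r (min(|v_r|/vscale, 1) - s_r)^2)`` with ``s_r`` the
    reaction activity scores; ``beta = 0`` reduces to the uniform sampler.
    Every retained draw must additionally pass the loop-law screen
    (rejection) when ``p`` is network-backed.  ``vscale`` defaults to the
    largest bound-window magnitude of the glucose exchange if present, else
    the largest mean absolute flux seen during burn-in.
    """
    scores_map = {}
    if ras is not None:
        scores_map = dict(getattr(ras, "scores", ras))
    score_idx = np.array(
        [i for i, r in enumerate(p.rxn_ids) if r in scores_map], dtype=int
    )
    scores = np.array([scores_map[p.rxn_ids[i]] for i in score_idx])

    basis = AffineBasis(p)
    rng = np.random.default_rng(seed)
    net = p.network

    if basis.dim == 0:
        warnings.warn("polytope is a single point; returning it for every draw")
        v = basis.point(np.zeros(0))
        return FluxPosterior(sample_id, condition, np.tile(v, (n, 1)), p.rxn_ids,
                             {"seed": seed, "beta": beta, "degenerate": True})

    t = basis.chebyshev_center()
    x = basis.point(t)

    if vscale is None:
        if "EX_glc" in p.windows:
            vscale = max(abs(p.windows["EX_glc"][0]), abs(p.windows["EX_glc"][1]))
        else:
            vscale = float(np.max(np.abs(x), initial=1.0))
        vscale = max(vscale, 1e-9)

    use_bias = beta != 0.0 and score_idx.size > 0
    logf = _bias_logdensity(x, scores, score_idx, beta, vscale) if use_bias else 0.0

    draws = np.empty((n, p.n_reactions))
    kept = accepted = proposed = rejected_loops = 0
    step = 0
    max_steps = 50 * (burn_in + n * thin) + 1000
    while kept < n:
        d = rng.standard_normal(basis.dim)
        d /= np.linalg.norm(d)
        w = basis.N @ d
        s_lo, s_hi = _chord(x, w, p.lb, p.ub)
        if s_hi > s_lo and np.isfinite(s_lo) and np.isfinite(s_hi):
            s = rng.uniform(s_lo, s_hi)
            x_new = x + s * w
            proposed += 1
            if use_bias:
                logf_new = _bias_logdensity(x_new, scores, score_idx, beta, vscale)
                if np.log(rng.uniform()) < logf_new - logf:
                    t, x, logf = t + s * d, x_new, logf_new
                    accepted += 1
            else:
                t, x = t + s * d, x_new
                accepted += 1
        step += 1
        if step % 1000 == 0:
            x = basis.point(t)
        if step > burn_in and (step - burn_in) % thin == 0:
            if net is None or loop_free(net, x, tol=loop_tol):
                draws[kept] = x
                kept += 1
            else:
                rejected_loops += 1
        if step > max_steps:
            raise RuntimeError(
                f"sampler could not retain {n} draws ({kept} kept, "
                f"{rejected_loops} loop rejections)"
            )
    acc_rate = accepted / max(proposed, 1)
    if acc_rate < acceptance_floor:
        log.warning(
            "Metropolis acceptance rate %.3f below floor %.3f "
            "(beta=%g, vscale=%g); posterior may mix slowly",
            acc_rate, acceptance_floor, beta, vscale,
        )
    return FluxPosterior(
        sample_id, condition, draws, p.rxn_ids,
        {
            "seed": int(seed) if np.isscalar(seed) else seed,
            "beta": beta, "vscale": vscale, "burn_in": burn_in, "thin": thin,
            "chain_steps": step, "acceptance_rate": acc_rate,
            "loop_rejections": rejected_loops,
        },
    )


def summarize_posterior(fp: FluxPosterior, quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)):
    """Per-reaction mean, sd and quantiles (mmol/gDW/hr) as a DataFrame."""
    import pandas as pd

    if fp.n_draws < 1:
        raise DegenerateInputError("posterior has no draws")
    data = {
        "mean": fp.draws.mean(axis=0),
        "sd": fp.draws.std(axis=0, ddof=0),
    }
    qs = np.quantile(fp.draws, quantiles, axis=0)
    for q, row in zip(quantiles, qs):
        data[f"q{q:g}"] = row
    return pd.DataFrame(data, index=pd.Index(fp.rxn_ids, name="reaction_id"))


def condition_mean(posteriors: list[FluxPosterior]) -> np.ndarray:
    """Cohort-level mean flux: average of per-sample posterior means."""
    return np.mean([fp.mean() for fp in posteriors], axis=0)


def mc_standard_error(x, n_batches: int = 20) -> float:
    """Batch-means Monte Carlo standard error of the mean of a chain."""
    x = np.asarray(x, dtype=float)
    nb = max(2, min(n_batches, len(x) // 2))
    usable = (len(x) // nb) * nb
    means = x[:usable].reshape(nb, -1).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(nb))
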