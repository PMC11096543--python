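"""The flux polytope: steady-state, bound and measurement-window constraints.

The feasible set is ``{v : A_eq v = b_eq, lb <= v <= ub}`` where ``A_eq``
contains the stoichiometric rows of the internal metabolites (``b_eq = 0``
for a network polytope) and the box absorbs default flux bounds, measured
exchange-rate windows, and the growth-rate window on the biomass reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._lp import lp_feasible
from .errors import InfeasibleError, ValidationError
from .network import MetabolicNetwork, stoichiometric_matrix


@dataclass
class FluxPolytope:
    """Constraint set over flux vectors, indexed by ``rxn_ids``.

    ``network`` is None for bare geometric polytopes (used in sampler
    calibration); thermodynamic loop screening then does not apply.
    ``windows`` records the measurement intervals applied on top of the
    default bounds, keyed by reaction id (metadata only — the intervals are
    already intersected into ``lb``/``ub``).
    """

    A_eq: np.ndarray
    b_eq: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    rxn_ids: list[str]
    network: MetabolicNetwork | None = None
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.A_eq = np.atleast_2d(np.asarray(self.A_eq, dtype=float))
        self.b_eq = np.asarray(self.b_eq, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self._index = {r: i for i, r in enumerate(self.rxn_ids)}
        if np.any(self.lb > self.ub + 1e-12):
            bad = [self.rxn_ids[i] for i in np.flatnonzero(self.lb > self.ub + 1e-12)]
            raise InfeasibleError(f"empty bound interval for {bad}")

    @property
    def n_reactions(self) -> int:
        return len(self.rxn_ids)

    def reaction_index(self, rxn_id: str) -> int:
        return self._index[rxn_id]

    def bounds_list(self):
        return list(zip(self.lb, self.ub))

    def contains(self, v, eq_tol: float = 1e-6, bound_tol: float = 1e-8) -> bool:
        v = np.asarray(v, dtype=float)
        if np.max(np.abs(self.A_eq @ v - self.b_eq), initial=0.0) > eq_tol:
            return False
        return bool(
            np.all(v >= self.lb - bound_tol) and np.all(v <= self.ub + bound_tol)
        )

    def is_feasible(self) -> bool:
        return lp_feasible(self.A_eq, self.b_eq, self.bounds_list())


def build_polytope(
    net: MetabolicNetwork,
    rates=None,
    mu: float | None = None,
    k: float = 2.0,
    delta: float = 0.05,
    extra_windows: dict[str, tuple[float, float]] | None = None,
) -> FluxPolytope:
    """Constrain ``net`` with measured exchange rates and growth.

    For every metabolite in ``rates`` (an :class:`~polyflux.rates.ExchangeRateSet`)
    the corresponding exchange reaction is restricted to the window
    ``[q - k*sem, q + k*sem]`` (a point when the SEM is zero or absent);
    the biomass reaction is restricted to ``[mu*(1-delta), mu*(1+delta)]``.
    Unmeasured exchanges keep their default bounds.  ``extra_windows`` maps
    reaction ids to intervals applied verbatim (used by the synthetic-data
    generator and by tests).

    Feasibility is certified by LP at construction.  If infeasible with the
    requested ``k``, the raised :class:`InfeasibleError` carries in ``detail``
    the smallest window half-width multiple ``k'`` that restores feasibility
    (found by bisection), or None if no widening helps.
    """
    S, _, rxn_ids = stoichiometric_matrix(net)
    b_eq = np.zeros(S.shape[0])
    lb = np.array([r.lower_bound for r in net.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in net.reactions], dtype=float)
    idx = {r: i for i, r in enumerate(rxn_ids)}

    def apply_windows(kk):
        lo, hi = lb.copy(), ub.copy()
        windows = {}
        if rates is not None:
            for met, q in rates.rates.items():
                ex = net.exchange_for_metabolite(met)
                if ex is None:
                    raise ValidationError(
                        f"no exchange reaction for measured metabolite {met!r}"
                    )
                sem = rates.sem.get(met, 0.0) if rates.sem else 0.0
                w = (q - kk * sem, q + kk * sem)
                j = idx[ex.id]
                lo[j] = max(lo[j], w[0])
                hi[j] = min(hi[j], w[1])
                windows[ex.id] = w
        if mu is not None:
            j = idx[net.biomass_reaction_id]
            w = (min(mu * (1 - delta), mu * (1 + delta)),
                 max(mu * (1 - delta), mu * (1 + delta)))
            lo[j] = max(lo[j], w[0])
            hi[j] = min(hi[j], w[1])
            windows[net.biomass_reaction_id] = w
        if extra_windows:
            for rid, w in extra_windows.items():
                j = idx[rid]
                lo[j] = max(lo[j], min(w))
                hi[j] = min(hi[j], max(w))
                windows[rid] = (min(w), max(w))
        return lo, hi, windows

    lo, hi, windows = apply_windows(k)
    if np.all(lo <= hi + 1e-12) and lp_feasible(S, b_eq, list(zip(lo, hi))):
        return FluxPolytope(A_eq=S, b_eq=b_eq, lb=lo, ub=hi, rxn_ids=rxn_ids,
                            network=net, windows=windows)

    # bisection for the smallest feasible window half-width multiple k'
    k_hi, k_prime = k if k > 0 else 1.0, None
    for _ in range(40):
        k_hi *= 2.0
        lo2, hi2, _ = apply_windows(k_hi)
        if np.all(lo2 <= hi2 + 1e-12) and lp_feasible(S, b_eq, list(zip(lo2, hi2))):
            k_prime = k_hi
            break
        if k_hi > 1e9:
            break
    if k_prime is not None:
        k_lo = k
        for _ in range(60):
            mid = 0.5 * (k_lo + k_prime)
            lo2, hi2, _ = apply_windows(mid)
            if np.all(lo2 <= hi2 + 1e-12) and lp_feasible(S, b_eq, list(zip(lo2, hi2))):
                k_prime = mid
            else:
                k_lo = mid
            if k_prime - k_lo < 1e-3 * max(1.0, k_prime):
                break
    raise InfeasibleError(
        "measurement windows are infeasible at k=%g%s"
        % (k, f"; smallest feasible k' ~ {k_prime:.4g}" if k_prime else
           " and no widening of the windows restores feasibility"),
        detail=k_prime,
    )
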