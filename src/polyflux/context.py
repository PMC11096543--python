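"""Context-specific model reduction: flux variability under the measured
constraints, and removal of reactions the measurements leave blocked."""

from __future__ import annotations

import copy
import logging

import numpy as np
import pandas as pd

from ._lp import solve_lp
from .errors import InfeasibleError, ValidationError
from .network import MetabolicNetwork
from .polytope import FluxPolytope

log = logging.getLogger(__name__)

BLOCKED_TOL = 1e-9  # mmol/gDW/hr


def flux_variability(p: FluxPolytope) -> pd.DataFrame:
    """LP minimum and maximum of every reaction's flux over the polytope.

    Returns a DataFrame indexed by reaction id with columns ``min``/``max``.
    """
    if not p.is_feasible():
        raise InfeasibleError("polytope is infeasible; no flux variability exists")
    bounds = p.bounds_list()
    n = p.n_reactions
    lo = np.empty(n)
    hi = np.empty(n)
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        lo[j] = solve_lp(c, A_eq=p.A_eq, b_eq=p.b_eq, bounds=bounds).fun
        hi[j] = -solve_lp(-c, A_eq=p.A_eq, b_eq=p.b_eq, bounds=bounds).fun
    # LP round-off can invert the pair by ~1e-9; restore the invariant
    lo, hi = np.minimum(lo, hi), np.maximum(lo, hi)
    return pd.DataFrame({"min": lo, "max": hi},
                        index=pd.Index(p.rxn_ids, name="reaction_id"))


def blocked_reactions(p: FluxPolytope, tol: float = BLOCKED_TOL) -> list[str]:
    fva = flux_variability(p)
    blocked = fva[np.maximum(fva["min"].abs(), fva["max"].abs()) < tol]
    return list(blocked.index)


def prune_network(net: MetabolicNetwork, p: FluxPolytope,
                  tol: float = BLOCKED_TOL) -> MetabolicNetwork:
    """Remove reactions that cannot carry flux under the measured constraints.

    A reaction is blocked when its achievable |flux| stays below ``tol``
    (default 1e-9 mmol/gDW/hr) over the whole polytope.  Orphaned metabolites
    are dropped with the reactions.  Removing only flux-zero reactions cannot
    change the achievable range of any retained reaction, so the pruned
    network stays feasible under the same constraints.
    """
    dead = set(blocked_reactions(p, tol=tol))
    if net.biomass_reaction_id in dead:
        raise InfeasibleError(
            "pruning would remove the biomass reaction: the measured "
            "constraints are inconsistent with growth"
        )
    if not dead:
        return net
    kept = [copy.deepcopy(r) for r in net.reactions if r.id not in dead]
    used = {m for r in kept for m in r.stoichiometry}
    mets = [copy.deepcopy(m) for m in net.metabolites if m.id in used]
    pruned = MetabolicNetwork(
        metabolites=mets, reactions=kept,
        biomass_reaction_id=net.biomass_reaction_id,
        compartments=list(net.compartments), id=net.id + "_pruned",
    )
    try:
        pruned.validate()
    except ValidationError as exc:  # pragma: no cover - indicates a logic bug
        raise InfeasibleError(f"pruned network failed validation: {exc}") from exc
    log.info("pruned %d blocked reactions, %d orphaned metabolites",
             len(dead), len(net.metabolites) - len(mets))
    return pruned


def polytope_for_network(p: FluxPolytope, net: MetabolicNetwork) -> FluxPolytope:
    """Restrict a polytope's windows/bounds to the reactions of ``net``
    (used after pruning so sampling runs on the reduced model)."""
    from .network import stoichiometric_matrix

    S, _, rxn_ids = stoichiometric_matrix(net)
    sel = [p.reaction_index(r) for r in rxn_ids]
    return FluxPolytope(
        A_eq=S, b_eq=np.zeros(S.shape[0]),
        lb=p.lb[sel], ub=p.ub[sel], rxn_ids=rxn_ids, network=net,
        windows={r: w for r, w in p.windows.items() if r in set(rxn_ids)},
    )
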