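"""Stoichiometric network data model with JSON serialization and SBML import.

A :class:`MetabolicNetwork` holds metabolites, reactions (stoichiometry, flux
bounds in mmol/gDW/hr, gene-protein-reaction rules) and a designated biomass
reaction.  Boundary metabolites (the medium side of exchange reactions) are
represented explicitly and excluded from mass balance, so the stoichiometric
matrix S has one row per *internal* metabolite and steady state reads
``S @ v == 0``.

The canonical on-disk format is a small JSON dialect (see
``docs/network_schema.md``); genome-scale models can be imported from
SBML Level 3 + fbc via cobra.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ValidationError

DEFAULT_IRREVERSIBLE_BOUNDS = (0.0, 1000.0)
DEFAULT_REVERSIBLE_BOUNDS = (-1000.0, 1000.0)


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``is_boundary`` marks medium-side pseudo-species that sit outside the
    mass balance (the sink/source end of exchange reactions).
    """

    id: str
    name: str = ""
    compartment: str = "cytosol"
    is_boundary: bool = False


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds and an optional GPR rule.

    Stoichiometry maps metabolite id to a signed coefficient (negative =
    consumed).  Bounds are in mmol/gDW/hr.  ``gpr`` is a boolean expression
    over gene ids ("g1 and (g2 or g3)"); empty string means no gene
    association.  Exchange reactions move exactly one internal metabolite
    across the system boundary; their flux is positive for secretion.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[0]
    upper_bound: float = DEFAULT_IRREVERSIBLE_BOUNDS[1]
    gpr: str = ""
    is_exchange: bool = False
    subsystem: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0.0 < self.upper_bound


@dataclass
class MetabolicNetwork:
    """Metabolites + reactions + biomass designation; houses S, l, u."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    compartments: list[str] = field(default_factory=lambda: ["cytosol", "mitochondrion", "extracellular"])
    id: str = "network"

    def __post_init__(self):
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}

    # -- lookups -----------------------------------------------------------

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if not m.is_boundary]

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchange_for_metabolite(self, met_id: str) -> Reaction | None:
        """The exchange reaction whose single internal metabolite is ``met_id``."""
        for r in self.exchange_reactions():
            internal = [m for m in r.stoichiometry if not self.metabolite(m).is_boundary]
            if internal == [met_id]:
                return r
        return None

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check every structural invariant; raise ValidationError listing all violations."""
        violations = []
        seen = set()
        for m in self.metabolites:
            if m.id in seen:
                violations.append(f"duplicate metabolite id {m.id!r}")
            seen.add(m.id)
            if m.compartment not in self.compartments:
                violations.append(
                    f"metabolite {m.id!r}: compartment {m.compartment!r} not declared"
                )
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                violations.append(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            if r.lower_bound > r.upper_bound:
                violations.append(
                    f"reaction {r.id!r}: lower_bound > upper_bound "
                    f"({r.lower_bound} > {r.upper_bound})"
                )
            if not r.stoichiometry:
                violations.append(f"reaction {r.id!r}: empty stoichiometry")
            for met_id, coeff in r.stoichiometry.items():
                if met_id not in self._met_index:
                    violations.append(
                        f"reaction {r.id!r}: unknown metabolite {met_id!r}"
                    )
                elif coeff == 0:
                    violations.append(
                        f"reaction {r.id!r}: zero coefficient for {met_id!r}"
                    )
                elif not math.isfinite(coeff):
                    violations.append(
                        f"reaction {r.id!r}: non-finite coefficient for {met_id!r}"
                    )
            if r.is_exchange:
                internal = [
                    m
                    for m in r.stoichiometry
                    if m in self._met_index and not self.metabolite(m).is_boundary
                ]
                if len(internal) != 1:
                    violations.append(
                        f"exchange reaction {r.id!r}: touches {len(internal)} "
                        "internal metabolites, expected exactly 1"
                    )
        if self.biomass_reaction_id not in self._rxn_index:
            violations.append(
                f"biomass reaction {self.biomass_reaction_id!r} not in network"
            )
        if not any(r.is_exchange for r in self.reactions):
            violations.append("network has no exchange reaction")
        if violations:
            raise ValidationError(violations)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "compartments": list(self.compartments),
            "biomass_reaction_id": self.biomass_reaction_id,
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "compartment": m.compartment,
                    "is_boundary": m.is_boundary,
                }
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": dict(r.stoichiometry),
                    "lower_bound": r.lower_bound,
                    "upper_bound": r.upper_bound,
                    "gpr": r.gpr,
                    "is_exchange": r.is_exchange,
                    "subsystem": r.subsystem,
                }
                for r in self.reactions
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def network_from_dict(data: dict) -> MetabolicNetwork:
    try:
        mets = [
            Metabolite(
                id=m["id"],
                name=m.get("name", ""),
                compartment=m.get("compartment", "cytosol"),
                is_boundary=bool(m.get("is_boundary", False)),
            )
            for m in data["metabolites"]
        ]
        rxns = [
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", DEFAULT_IRREVERSIBLE_BOUNDS[0])),
                upper_bound=float(r.get("upper_bound", DEFAULT_IRREVERSIBLE_BOUNDS[1])),
                gpr=r.get("gpr", ""),
                is_exchange=bool(r.get("is_exchange", False)),
                subsystem=r.get("subsystem", ""),
            )
            for r in data["reactions"]
        ]
        net = MetabolicNetwork(
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=data["biomass_reaction_id"],
            compartments=list(data.get("compartments", ["cytosol", "mitochondrion", "extracellular"])),
            id=data.get("id", "network"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed network JSON: {exc!r}") from exc
    return net


def load_network(path, format: str = "json") -> MetabolicNetwork:
    """Load and validate a network from ``path``.

    ``format`` is ``"json"`` (canonical dialect) or ``"sbml"`` (Level 3 + fbc,
    imported via cobra).  Raises :class:`FormatError` on parse failure and
    :class:`ValidationError` (listing every violation) on invariant failure.
    """
    if format == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
        net = network_from_dict(data)
    elif format == "sbml":
        net = _load_sbml(path)
    else:
        raise FormatError(f"unknown network format {format!r}")
    net.validate()
    return net


def _load_sbml(path) -> MetabolicNetwork:
    """Map an SBML/fbc model onto the package data model.

    SBML species become metabolites (boundaryCondition → is_boundary), SBML
    reactions become reactions, and fbc gene-product associations become GPR
    strings.  cobra's convention of exchange reactions without an explicit
    boundary species is preserved by synthesizing a boundary partner.
    """
    import cobra

    try:
        model = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises a zoo of parse errors
        raise FormatError(f"{path}: SBML parse failed ({exc})") from exc

    compartments = sorted(set(model.compartments) | {"boundary"})
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment=m.compartment or compartments[0],
            is_boundary=getattr(m, "boundary_condition", False),
        )
        for m in model.metabolites
    ]
    met_ids = {m.id for m in mets}
    rxns = []
    extra_boundary = []
    exchange_ids = {r.id for r in model.exchanges}
    for r in model.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()}
        is_ex = r.id in exchange_ids or r.boundary
        if is_ex and len(stoich) == 1:
            # synthesize the medium-side species so the dialect's exchange
            # invariant (one internal + one boundary metabolite) holds
            (met_id,) = stoich
            bid = met_id + "_bnd"
            if bid not in met_ids:
                extra_boundary.append(
                    Metabolite(id=bid, name="", compartment="boundary", is_boundary=True)
                )
                met_ids.add(bid)
            stoich[bid] = -stoich[met_id]
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry=stoich,
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                gpr=str(r.gene_reaction_rule or ""),
                is_exchange=is_ex,
                subsystem=r.subsystem or "",
            )
        )
    biomass = None
    for r in model.reactions:
        if r.objective_coefficient:
            biomass = r.id
            break
    if biomass is None:
        for r in model.reactions:
            if "biomass" in r.id.lower():
                biomass = r.id
                break
    if biomass is None:
        raise FormatError(f"{path}: no objective/biomass reaction found")
    return MetabolicNetwork(
        metabolites=mets + extra_boundary,
        reactions=rxns,
        biomass_reaction_id=biomass,
        compartments=compartments,
        id=model.id or "sbml_model",
    )


def stoichiometric_matrix(network: MetabolicNetwork):
    """Dense S with rows = internal metabolites, columns = reactions.

    Returns ``(S, met_ids, rxn_ids)`` where ``S[m, r]`` is the coefficient of
    internal metabolite ``met_ids[m]`` in reaction ``rxn_ids[r]``.
    """
    internal = network.internal_metabolites()
    row = {m.id: i for i, m in enumerate(internal)}
    S = np.zeros((len(internal), len(network.reactions)))
    for j, rxn in enumerate(network.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            i = row.get(met_id)
            if i is not None:
                S[i, j] = coeff
    return S, [m.id for m in internal], [r.id for r in network.reactions]
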