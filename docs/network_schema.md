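# Network JSON dialect

The canonical on-disk format for metabolic networks in this package is a
single JSON object.  It is deliberately small so that curated models remain
human-diffable; genome-scale models can instead be imported from SBML
Level 3 + fbc (`load_network(path, format="sbml")`).

```json
{
 "id": "toy",
 "compartments": ["cytosol", "extracellular"],
 "biomass_reaction_id": "BIOMASS",
 "metabolites": [
  {"id": "glc", "name": "D-glucose", "compartment": "cytosol",
   "is_boundary": false},
  {"id": "glc_b", "name": "glucose (medium)", "compartment": "extracellular",
   "is_boundary": true}
 ],
 "reactions": [
  {"id": "EX_glc",
   "stoichiometry": {"glc": -1.0, "glc_b": 1.0},
   "lower_bound": -1000.0, "upper_bound": 1000.0,
   "gpr": "", "is_exchange": true, "subsystem": "exchange"}
 ]
}
```

## Fields

* `metabolites[].id` — unique short id; `stoichiometry` keys must resolve
  to declared metabolites.
* `metabolites[].compartment` — must appear in the top-level
  `compartments` list.
* `metabolites[].is_boundary` — marks the medium side of an exchange
  reaction.  Boundary metabolites are excluded from mass balance: the
  stoichiometric matrix `S` has one row per non-boundary metabolite, and
  steady state is `S v = 0`.
* `reactions[].stoichiometry` — metabolite id → signed coefficient;
  negative = consumed.  No zero coefficients; at least one entry.
* `reactions[].lower_bound` / `upper_bound` — flux bounds in mmol/gDW/hr
  with `lower_bound <= upper_bound`.  Convention for defaults:
  irreversible `[0, 1000]`, reversible `[-1000, 1000]`; curated capacity
  bounds may be narrower.
* `reactions[].gpr` — boolean gene-protein-reaction rule over gene ids
  (`"Hk1 or Hk2"`, `"Gapdh and Pgk1"`, parentheses allowed, keywords
  case-insensitive).  Empty string = no gene association.
* `reactions[].is_exchange` — exchange pseudo-reactions move exactly one
  non-boundary metabolite across the system boundary.  Flux sign
  convention: **positive = secretion into the medium, negative = uptake**.
* `biomass_reaction_id` — must name an existing reaction.  Its flux is in
  1/hr (growth rate), so its stoichiometric coefficients are mmol of
  precursor per gram dry weight of new biomass.

## Validation

`load_network` checks every invariant above and raises a validation error
listing *all* violations found, or a format error naming the offending
element when the file does not parse.

## SBML import mapping

species → metabolite (`boundaryCondition` → `is_boundary`); reaction →
reaction with its fbc bounds; fbc gene-product association → `gpr` string;
the fbc objective (or, failing that, a reaction whose id contains
"biomass") → `biomass_reaction_id`.  cobra-style exchange reactions written
with a single metabolite get a synthesized `*_bnd` boundary partner so the
dialect's exchange invariant holds.  SBML export is not supported.
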