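"""Core metabolic network of an activated CD4+ T cell.

A deliberately compact model of the pathways that dominate carbon and energy
flow in proliferating T cells: glycolysis with lactate secretion (Warburg
effect), the oxidative pentose phosphate branch returning to glycolysis, the
full TCA cycle with anaplerotic pyruvate carboxylase and cataplerotic
NAD-linked malic enzyme, glutaminolysis with glutamate secretion, exchange of
alanine/aspartate/glycine/serine, a lumped oxidative phosphorylation step
regenerating ATP from O2, a glutathione-coupled NADPH sink, and a biomass
reaction consuming precursors plus ATP.

Lumping conventions: single shared NAD(H), NADP(H), ATP/ADP and FAD(H2)
pools (no shuttle reactions); transport steps are folded into the consuming
pathway step, so a reaction may span the cytosol/mitochondrion labels of its
metabolites.  GPR rules use mouse gene symbols as placeholder gene ids.
"""

from __future__ import annotations

from .network import MetabolicNetwork, Metabolite, Reaction

# well-known ids used by downstream analyses (pyruvate partitioning, oxPPP share)
GLUCOSE_EXCHANGE = "EX_glc"
LACTATE_EXCHANGE = "EX_lac"
OXPPP_ENTRY = "G6PD"
PYRUVATE = "pyr"
LACTATE = "lac"
BIOMASS = "BIOMASS"

_C = "cytosol"
_M = "mitochondrion"
_E = "extracellular"

_INTERNAL_METS = [
    # glycolysis / PPP
    ("glc", "D-glucose", _C), ("g6p", "glucose 6-phosphate", _C),
    ("f6p", "fructose 6-phosphate", _C), ("fdp", "fructose 1,6-bisphosphate", _C),
    ("gap", "glyceraldehyde 3-phosphate", _C), ("pg3", "3-phosphoglycerate", _C),
    ("pyr", "pyruvate", _C), ("lac", "L-lactate", _C),
    ("p5p", "pentose 5-phosphate pool", _C),
    # TCA
    ("accoa", "acetyl-CoA (lumped)", _M), ("cit", "citrate", _M),
    ("akg", "2-oxoglutarate", _M), ("succ", "succinate", _M),
    ("fum", "fumarate", _M), ("mal", "L-malate", _M), ("oaa", "oxaloacetate", _M),
    # amino acids / nitrogen
    ("gln", "L-glutamine", _C), ("glu", "L-glutamate", _C),
    ("ala", "L-alanine", _C), ("asp", "L-aspartate", _C),
    ("ser", "L-serine", _C), ("gly", "glycine", _C), ("nh4", "ammonium", _C),
    # cofactors and gases
    ("nad", "NAD+", _C), ("nadh", "NADH", _C),
    ("nadp", "NADP+", _C), ("nadph", "NADPH", _C),
    ("atp", "ATP", _C), ("adp", "ADP", _C),
    ("fad", "FAD", _M), ("fadh2", "FADH2", _M),
    ("o2", "oxygen", _C), ("co2", "carbon dioxide", _C),
]

# metabolites with an exchange reaction (medium side gets an explicit boundary twin)
_EXCHANGED = ["glc", "gln", "ser", "o2", "lac", "glu", "ala", "asp", "gly", "co2", "nh4"]

REV = (-1000.0, 1000.0)
IRR = (0.0, 1000.0)

# (id, stoichiometry, (lb, ub), gpr, subsystem)
_INTERNAL_RXNS = [
    ("HEX1", {"glc": -1, "atp": -1, "g6p": 1, "adp": 1}, IRR,
     "Hk1 or Hk2", "glycolysis"),
    ("PGI", {"g6p": -1, "f6p": 1}, REV, "Gpi1", "glycolysis"),
    ("PFK", {"f6p": -1, "atp": -1, "fdp": 1, "adp": 1}, IRR,
     "Pfkl or Pfkm or Pfkp", "glycolysis"),
    ("FBA", {"fdp": -1, "gap": 2}, REV, "Aldoa and Tpi1", "glycolysis"),
    ("GAPD", {"gap": -1, "nad": -1, "adp": -1, "pg3": 1, "nadh": 1, "atp": 1}, REV,
     "Gapdh and Pgk1", "glycolysis"),
    ("PYK", {"pg3": -1, "adp": -1, "pyr": 1, "atp": 1}, IRR,
     "Eno1 and Pkm", "glycolysis"),
    ("LDH", {"pyr": -1, "nadh": -1, "lac": 1, "nad": 1}, REV,
     "Ldha or Ldhb", "glycolysis"),
    ("G6PD", {"g6p": -1, "nadp": -2, "p5p": 1, "co2": 1, "nadph": 2}, IRR,
     "G6pdx and Pgls and Pgd", "oxidative PPP"),
    ("TKT", {"p5p": -3, "f6p": 2, "gap": 1}, REV,
     "Tkt and Taldo1", "non-oxidative PPP"),
    ("PDH", {"pyr": -1, "nad": -1, "accoa": 1, "co2": 1, "nadh": 1}, IRR,
     "Pdha1 and Pdhb and Dlat", "TCA cycle"),
    ("CS", {"accoa": -1, "oaa": -1, "cit": 1}, IRR, "Cs", "TCA cycle"),
    ("IDH", {"cit": -1, "nad": -1, "akg": 1, "co2": 1, "nadh": 1}, IRR,
     "Aco2 and (Idh2 or Idh3a)", "TCA cycle"),
    ("AKGD", {"akg": -1, "nad": -1, "adp": -1, "succ": 1, "co2": 1, "nadh": 1, "atp": 1},
     IRR, "Ogdh and Dlst and Suclg1", "TCA cycle"),
    ("SUCD", {"succ": -1, "fad": -1, "fum": 1, "fadh2": 1}, REV,
     "Sdha and Sdhb", "TCA cycle"),
    ("FUM", {"fum": -1, "mal": 1}, REV, "Fh1", "TCA cycle"),
    ("MDH", {"mal": -1, "nad": -1, "oaa": 1, "nadh": 1}, REV, "Mdh2", "TCA cycle"),
    ("PC", {"pyr": -1, "co2": -1, "atp": -1, "oaa": 1, "adp": 1}, (0.0, 0.05),
     "Pcx", "anaplerosis"),
    ("ME2", {"mal": -1, "nad": -1, "pyr": 1, "co2": 1, "nadh": 1}, (0.0, 0.05),
     "Me2", "anaplerosis"),
    ("GLS", {"gln": -1, "glu": 1, "nh4": 1}, IRR, "Gls", "glutaminolysis"),
    ("GLUD", {"glu": -1, "nad": -1, "akg": 1, "nadh": 1, "nh4": 1}, REV,
     "Glud1", "glutaminolysis"),
    ("ALT", {"pyr": -1, "glu": -1, "ala": 1, "akg": 1}, REV,
     "Gpt or Gpt2", "amino acid metabolism"),
    ("AST", {"oaa": -1, "glu": -1, "asp": 1, "akg": 1}, REV,
     "Got1 or Got2", "amino acid metabolism"),
    ("PSER", {"pg3": -1, "glu": -1, "nad": -1, "ser": 1, "akg": 1, "nadh": 1}, IRR,
     "Phgdh and Psat1 and Psph", "amino acid metabolism"),
    ("SHMT", {"ser": -1, "gly": 1, "co2": 1}, IRR,
     "Shmt1 or Shmt2", "amino acid metabolism"),
    ("OXPHOS_NADH",
     {"nadh": -1, "o2": -0.5, "adp": -2.5, "nad": 1, "atp": 2.5}, IRR,
     "Ndufa1 and Uqcrc1 and Cox4i1 and Atp5f1a", "oxidative phosphorylation"),
    ("OXPHOS_FADH2",
     {"fadh2": -1, "o2": -0.5, "adp": -1.5, "fad": 1, "atp": 1.5}, IRR,
     "Sdha and Uqcrc1 and Cox4i1 and Atp5f1a", "oxidative phosphorylation"),
    ("GSH_REDOX", {"nadph": -1, "nadp": 1}, (0.0, 2.0),
     "Gsr and Gpx1", "glutathione cycle"),
    # curated non-growth-associated maintenance range
    ("ATPM", {"atp": -1, "adp": 1}, (1.0, 10.0), "", "maintenance"),
    (BIOMASS,
     {"g6p": -0.05, "p5p": -0.12, "accoa": -0.65, "oaa": -0.30,
      "glu": -0.30, "gln": -0.35, "asp": -0.25, "ser": -0.20, "gly": -0.25,
      "ala": -0.25, "nadph": -1.0, "atp": -30.0, "adp": 30.0, "nadp": 1.0},
     IRR, "", "biomass"),
]


def core_tcell_network() -> MetabolicNetwork:
    """Build the packaged core T-cell network (validated on construction)."""
    mets = [Metabolite(id=i, name=n, compartment=c) for i, n, c in _INTERNAL_METS]
    mets += [
        Metabolite(id=m + "_b", name=m + " (medium)", compartment=_E, is_boundary=True)
        for m in _EXCHANGED
    ]
    rxns = [
        Reaction(id=rid, stoichiometry={k: float(v) for k, v in st.items()},
                 lower_bound=b[0], upper_bound=b[1], gpr=gpr, subsystem=sub)
        for rid, st, b, gpr, sub in _INTERNAL_RXNS
    ]
    # exchange flux convention: positive = secretion into the medium
    for m in _EXCHANGED:
        rxns.append(
            Reaction(id=f"EX_{m}", stoichiometry={m: -1.0, m + "_b": 1.0},
                     lower_bound=REV[0], upper_bound=REV[1],
                     is_exchange=True, subsystem="exchange")
        )
    net = MetabolicNetwork(
        metabolites=mets, reactions=rxns, biomass_reaction_id=BIOMASS,
        compartments=[_C, _M, _E], id="tcell_core",
    )
    net.validate()
    return net
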