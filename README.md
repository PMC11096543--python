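# polyflux

Bayesian inference of intracellular metabolic fluxes in proliferating
CD4+ T cells from culture measurements, and comparison of the inferred
flux state between two cohorts (e.g. healthy-control B6 vs lupus-prone
mice).

Activated T cells rewire their metabolism — aerobic glycolysis with
lactate export, glutaminolysis, NADPH regeneration through the oxidative
pentose phosphate pathway — but no single omics readout measures reaction
*rates*. polyflux integrates what a cell-culture lab can actually measure:

* cell counts at two or more timepoints → specific growth rate μ (per hour),
* supernatant metabolite concentrations (mM) → specific consumption and
  release (CORE) rates `q = ΔC·V / (AUC·w)` in mmol/gDW/hr, where AUC is
  the area under the fitted exponential cell-number curve and `w` the dry
  mass per cell,
* gene expression → per-reaction activity scores through gene-protein-
  reaction (GPR) rules (AND = min over complex subunits, OR = sum over
  isozymes).

Given a stoichiometric network S, the steady-state constraint `S·v = 0`,
flux bounds `l ≤ v ≤ u`, windows `q ± k·SEM` on each measured exchange
flux, and `μ(1±δ)` on the biomass flux define a convex **flux polytope**.
polyflux draws posterior flux samples from it by hit-and-run MCMC with a
Metropolis bias toward the activity scores,

    π(v) ∝ exp( −β Σ_r ( min(|v_r|/vscale, 1) − s_r )² ),

rejecting any draw that carries circulation around an internal cycle
(thermodynamic loop law, checked by a sign-constrained LP).  Cohorts are
compared per animal: fraction of reactions with higher flux, the fraction
of pyruvate excreted as lactate, the share of glucose entering the
oxidative PPP, and exact (enumerated) Wilcoxon rank-sum p-values for the
small-n animal design.

A compact curated T-cell network (glycolysis, oxidative PPP, TCA cycle,
glutaminolysis, anaplerosis, amino-acid exchange, lumped oxidative
phosphorylation, glutathione NADPH sink, biomass) ships with the package
(`docs/network_schema.md` documents the JSON dialect; SBML Level 3 + fbc
models can be imported).  A synthetic-data module fabricates complete
experiments from a known ground-truth flux vector so the whole chain is
testable without animal data — see `docs/methods.md` for the model,
parameter choices, and limitations.

## Worked example

Run the full pipeline on the default synthetic scenario (two conditions,
4 mice each; condition "TC" is a globally 1.25× up-shifted metabolic
state):

```bash
polyflux run-all --seed 1 --n 200 --out demo/
```

This simulates the culture data, estimates rates, scores expression,
prunes the network, samples 200 posterior flux vectors per mouse, and
prints:

```
wrote demo/summary.json
fraction of reactions higher in TC: 0.950
```

`demo/summary.json` holds the cohort statistics from this run:

* `fraction_reactions_higher_in_b: 0.95` — 95% of reactions carry more
  flux in the up-shifted condition, recovering the generative contrast.
* pyruvate→lactate fraction `0.764 ± 0.009` (B6) vs `0.726 ± 0.007` (TC),
  exact Wilcoxon p = 0.0571 — both cohorts excrete ~3/4 of their pyruvate
  as lactate (the Warburg phenotype); a global flux up-shift leaves the
  *partitioning* nearly unchanged, which is exactly what this statistic
  is designed to detect.
* oxPPP fraction `0.52 ± 0.20` vs `0.51 ± 0.09`, p = 0.886 — the share of
  glucose entering the oxidative PPP, with animal-to-animal scatter
  reflecting the 3% concentration noise propagated through a 25 mM
  glucose background.

Each stage is also exposed separately (`simulate`, `corerates`, `ras`,
`prune`, `sample`, `compare`), reading and writing plain CSV/JSON so any
stage can be fed real data in the documented schemas; `provenance.json`
records config, seeds, versions and artifact checksums, and a rerun with
the same master seed is byte-identical.

Library use mirrors the CLI:

```python
from polyflux import (core_tcell_network, build_polytope, sample_posterior,
                      score_network, estimate_sample_rates)
```

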