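# Methods

## Overview

polyflux estimates intracellular metabolic fluxes of proliferating
(anti-CD3/CD28-activated) CD4+ T cells from three kinds of culture
measurements — cell counts over time, supernatant metabolite
concentrations, and gene expression — and compares the inferred flux
state between two cohorts (e.g. healthy-control vs lupus-prone mice).
The chain is:

1. **CORE rates.** Specific consumption/release rates and the growth rate
   are estimated from the culture time courses.
2. **Flux polytope.** The stoichiometric network plus the measured rates
   define a convex set of flux vectors compatible with steady state.
3. **Context pruning.** Reactions that cannot carry flux under the
   measurements are removed.
4. **Posterior sampling.** Flux vectors are drawn from the polytope by
   Markov chain Monte Carlo, biased toward transcriptome-derived reaction
   activity scores and screened for thermodynamic (loop-law) feasibility.
5. **Comparison.** Cohort-level statistics (share of reactions with higher
   flux, pyruvate-to-lactate partitioning, oxidative-PPP share of glucose)
   with exact rank-sum tests across animals.

## Rate estimation

Cells in batch culture are modeled as exponential,
`N(t) = N0 exp(mu t)`.  With two count timepoints mu has the closed form
`ln(N2/N1)/(t2-t1)`; with more, the least-squares slope of `ln N` vs time
is used.  The specific exchange rate of metabolite *m* is

```
q_m = dC_m [mM] * V [L] / ( AUC [cell h] * w [g/cell] )   [mmol/gDW/hr]
```

where `dC_m` is the net supernatant concentration change between the first
and last sampling times, `V` the culture volume, `w` the dry mass per cell
(default 30 pg — the per-gram-dry-weight convention needs an explicit
conversion factor and this is a typical lymphocyte value; it is
configurable), and AUC the integral of the fitted exponential between the
same two times (`(N(t2)-N(t1))/mu`, with the continuous limit `N·Δt` as
`mu → 0`).  Secretion is positive, consumption negative.  A trapezoidal
AUC over the raw counts is available by flag for clearly non-exponential
count profiles.  On noiseless data this inversion is exact — the
synthetic-data tests verify recovery to 1e-6 relative error.

Replicate animals of one condition are estimated independently and then
aggregated (mean and SEM = sd/sqrt(n) per metabolite).

## The flux polytope

For the stoichiometric matrix S over internal metabolites, steady state
requires `S v = 0`.  The feasible set is intersected with per-reaction
bounds and with measurement windows: each measured exchange rate `q`
constrains its exchange flux to `[q - k*sem, q + k*sem]` (default `k = 2`
SEMs; a point when the SEM is zero), and the growth rate constrains the
biomass flux to `mu (1 ± delta)` (default `delta = 5%`).  Feasibility is
certified by LP at construction; when the windows are jointly infeasible
— which happens for individual animals when independent measurement noise
violates a stoichiometric dependency among the measured rates — the error
reports the smallest window multiple `k'` that restores feasibility
(bisection), and the pipeline's sampling stage retries at `1.1 k'`,
recording the widening in the posterior metadata.

## Sampling

Sampling runs in the null-space parameterization `v = v0 + N t` of the
full equality system (stoichiometry plus any degenerate, point-width
windows), so mass balance holds to machine precision by construction.
Hit-and-run proposals pick a random direction in t-space and a uniform
point on the feasible chord; a Metropolis filter targets

```
pi(v) ∝ exp( -beta * sum_r ( min(|v_r|/vscale, 1) - s_r )^2 )
```

where `s_r` ∈ [0,1] are reaction activity scores and `vscale` normalizes
fluxes (default: the glucose-uptake magnitude, the natural scale of the
network's largest flux).  `beta = 0` recovers the uniform sampler, whose
calibration is tested against closed-form moments on a simplex.  Chains
start at the Chebyshev center of the polytope; defaults are a burn-in of
10^4 steps with thinning 10^2 (tests and the acceptance script use shorter
chains on the small core network, where mixing is fast).  Every retained
draw must pass the loop-law screen (below); draws are deterministic given
the seed.

### Reaction activity scores

GPR rules are parsed into AND/OR trees; AND aggregates by minimum
(limiting complex subunit), OR by sum (isozymes add capacity).  This is
the common convention for expression-to-reaction mapping; the raw
aggregates are normalized to `min(1, raw / P99)` against the 99th
percentile of positive aggregates so a single dominant transcript cannot
flatten the rest.  Reactions with no GPR get a neutral score of 0.5 so
the bias neither rewards nor punishes them; exchange pseudo-reactions and
the biomass reaction are not scored at all — they are not
enzyme-catalyzed, and their fluxes are constrained by measurements, not
transcripts.  Genes missing from a profile score 0 (absence of evidence
treated as low activity; configurable).  Scores are invariant to global
rescaling of the expression profile.

### Loop law

A flux vector must not contain circulation around internal cycles
(flux loops that satisfy mass balance but would violate the second law).
The check solves an LP: fix exchange and biomass fluxes, confine every
internal reaction to the interval between 0 and its current flux (signs
cannot flip), and minimize total internal |flux|.  The vector is loop-free
iff the optimum equals its own internal |flux| sum (tolerance 1e-6
relative); otherwise the minimizer is the repaired, loop-free vector with
identical exchanges, available as `remove_loops` (used by the ground-truth
generator and as a diagnostic).  Sampling handles loops by rejection of
retained draws.  Note a structural caveat: on networks that contain a
topological cycle with reversible bounds, loop-free states form a
measure-zero subset and rejection cannot terminate — the sampler raises
with its rejection count.  The packaged core network contains no internal
cycle, so there rejection is a guarantee rather than a filter; genome-scale
imports with many loops would need the repair route instead.

## Context pruning

Flux variability analysis (per-reaction LP min/max over the polytope)
identifies blocked reactions — achievable |flux| below 1e-9 mmol/gDW/hr
under the measured constraints — which are removed along with orphaned
metabolites.  Removing flux-zero reactions cannot change any retained
reaction's achievable range, so pruning is idempotent and
feasibility-preserving; attempting to prune the biomass reaction (i.e.
measurements inconsistent with any growth) is an error, not a silent
removal.  Expression does not enter pruning; it only biases sampling.

## Condition comparison

Each animal contributes one posterior-mean flux vector.  Cohort statistics:

* **fraction higher** — share of reactions whose cohort-mean |flux| is
  strictly larger in condition B, reactions at zero flux in both cohorts
  excluded.  Absolute values make the statistic indifferent to
  reversible-direction conventions.
* **pyruvate→lactate fraction** — lactate-directed pyruvate consumption
  divided by total pyruvate production, per animal, on the posterior mean.
* **oxPPP fraction** — flux through the oxidative-PPP entry
  (glucose-6-phosphate dehydrogenase) over glucose uptake magnitude.
* **exact Wilcoxon rank-sum** — two-sided p by enumeration of all
  C(nA+nB, nA) group assignments with midranks for ties; designed for the
  n = 4 vs 4 animal design where asymptotic p-values are meaningless.

## Synthetic data generator

The generator exists so every stage is testable end-to-end without animal
data.  It draws a loop-free ground-truth flux vector v* from the core
network under physiological windows (glucose uptake 0.8–1.2 and glutamine
0.25–0.8 mmol/gDW/hr, growth 0.02–0.04 /hr, oxidative-PPP entry 10–30% of
glucose uptake, minor anaplerotic cycling), then forward-simulates per
animal: counts `N0 exp(mu* t)` at 48 h and 72 h, supernatant
concentrations at 0/48/72 h via the closed-form AUC relation (medium: 25 mM
glucose, 10 mM glutamine, 2 mM serine, supplemented amino acids), and
per-gene expression encoding each reaction's capped normalized |v*|
distributed down its GPR tree (OR branches split the level, AND subunits
share it) so that score computation recovers a flux-aligned profile —
that alignment is the generator's purpose, and an "uninformative
expression" switch disables it for robustness checks.  Noise is
multiplicative: 3% sd on concentrations, 5% on counts, lognormal
sigma 0.3 on expression — chosen so that four animals per condition give
SEM bars of a few percent to ~15% on the high-flux rates.  Oxygen uptake
is included among the measured rates (as the dissolved-oxygen decline an
extracellular-flux analyzer reports); without it the split between
glycolysis and the oxidative PPP is unidentifiable from supernatant data
alone, since along that degree of freedom the oxygen flux is the only
measurable quantity that moves.  Seeding density is 7.5e5 cells/mL in 1 mL,
keeping nutrients above depletion in both conditions while the day-2/3
concentration changes stay well above the noise floor; depletion, if
forced by non-default settings, floors the concentration at zero and flags
the metabolite.

What the generator does **not** emulate: single-cell count sparsity
(expression is emitted as pseudo-bulk levels), medium evaporation or
feeding, non-exponential growth phases, measurement-batch effects, and
inter-animal biological variability beyond measurement noise (every mouse
shares the condition's v*).  Passing recovery tests therefore demonstrate
correctness of the inference machinery under the stated noise model, not
robustness to those real-data complications.

The two-condition generator multiplies v* reaction-wise (key `"*"` sets
the default multiplier), re-projects onto the balanced polytope
(L1-nearest feasible point, with the biomass flux pinned at its intended
value so the projection cannot absorb imbalances by inflating
proliferation), and removes any loop.  The default contrast multiplies all
fluxes by 1.25, mimicking a globally more active metabolic state with
faster proliferation.

## The packaged core network

40 reactions, 33 internal metabolites: glycolysis (GLUT1-mediated uptake
folded into hexokinase's substrate supply, through pyruvate kinase),
lactate dehydrogenase and lactate export (Warburg effect), the oxidative
PPP branch (lumped G6PD–6PGL–6PGD entry, non-oxidative return to
glycolysis), the full TCA cycle, pyruvate carboxylase and NAD-linked malic
enzyme (anaplerosis/cataplerosis — also what gives the network enough
flexibility that independently noisy measured rates remain jointly
feasible), glutaminolysis with glutamate export, alanine/aspartate/glycine
secretion and serine uptake, lumped oxidative phosphorylation (P/O 2.5 for
NADH, 1.5 for FADH2), a glutathione-cycle NADPH sink, ATP maintenance
(1–10 mmol/gDW/hr), and a biomass reaction consuming precursors plus
30 mmol ATP per gDW.  Cofactor pools (NAD(H), NADP(H), ATP/ADP, FAD(H2))
are shared across compartments — shuttles are not resolved — and transport
steps are folded into the consuming pathway reaction.  GPRs use mouse gene
symbols as placeholder gene ids.  Capacity bounds on the anaplerotic pair
(≤ 0.05) and the glutathione cycle (≤ 2) keep the directions that no
supernatant measurement can see within a physiological range; together
with the measured rates this makes every reaction carrying ≥ 5% of
glucose uptake identifiable, which the recovery tests assert at 20%
relative error.

## Numerical choices

* LPs: scipy's HiGHS interface throughout (feasibility certificates,
  variability analysis, Chebyshev centers, loop LPs, L1 projections).
* Equality folding: bound intervals narrower than 1e-9 are treated as
  equality constraints and folded into the null-space parameterization.
* Conservation tolerances: |S v| ≤ 1e-6 and bound violations ≤ 1e-8 are
  asserted over entire posteriors (achieved ~1e-14 in practice).
* Chord endpoints are used as-is; float drift is controlled by refreshing
  `v0 + N t` every 1000 steps.
* Degenerate (point) polytopes return their single point with a warning.
* Monte Carlo standard errors in tests use batch means; calibration
  quantities derived from replicate pipeline runs estimate their MC error
  across replicates because reaction-level calls are correlated through
  the pathway structure.

## Known limitations

* Loop handling by rejection does not scale to loop-rich genome-scale
  networks (see above); `remove_loops` is the provided alternative.
* The bias strength `beta` (default 5) is a modeling choice; the posterior
  is a biased sampling scheme, not a calibrated likelihood — credible
  intervals should be read as plausibility envelopes.
* Exchange-rate estimation assumes a closed batch culture (no feeding or
  evaporation correction) and exponential growth between sampling times.
* The comparison's "fraction higher" depends on cohort means of posterior
  means; with four animals per cohort it is descriptive, and only the
  derived per-animal fractions carry exact p-values.
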