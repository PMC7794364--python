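# Methods

This document describes the mathematical formulation behind `gbmflux`,
the default parameter values with units and rationale, and the known
limitations of the synthetic data generator. Everything here is part
of the package contract: the test suite pins these behaviors.

## 1. Model representation

A `MetabolicModel` is an immutable collection of metabolites and
reactions. Each reaction carries a stoichiometry (metabolite id →
coefficient), flux bounds in mmol/gDW/h, and an optional
gene–protein–reaction (GPR) boolean rule over gene symbols
(`and`/`or`/parentheses, with `and` binding tighter). A reaction
touching exactly one metabolite is classified as an exchange. All
mutating operations (`with_reaction_bounds`, `add_reaction`,
`with_objective`) are copy-on-write and leave the original untouched.

IO supports a COBRA-compatible JSON dialect (cross-readable by
cobrapy, which the test suite uses as an independent oracle), a plain
TSV pair, and SBML via the optional `python-libsbml` extra.
`validate_model` reports structural problems (duplicate ids, inverted
bounds, unknown metabolites, empty stoichiometries, dangling
objectives) as data rather than raising, so callers can triage.

## 2. Flux balance and flux variability analysis

FBA solves `max c·v` subject to `S v = 0`, `lb ≤ v ≤ ub` with scipy's
HiGHS solver. Infeasible and unbounded statuses are surfaced
verbatim, never coerced to zero.

FVA minimizes and maximizes each reaction flux under the same
constraints plus an optional sub-optimality row `c·v ≥ γ·z*`, where
`z*` is the FBA optimum and `γ ∈ [0, 1]` (`FVAConfig.gamma`,
default 1). `γ = 0` explores the entire feasible polytope and is the
setting used for contextualized models, whose phenotype is expressed
through bounds rather than an objective. Ranges at higher `γ` are
always nested inside ranges at lower `γ`. Per-reaction LP failures
are collected in `FVAResult.failed` (id → message) instead of
aborting the sweep.

## 3. ACHR flux sampling

`achr_sample` implements artificial-centering hit-and-run on the flux
polytope `{v : S v = 0, lb ≤ v ≤ ub}`:

* **Affine hull.** Directions are drawn in the null space of `S`
  augmented with an identity row for every coordinate whose bounds
  pin it (`ub − lb ≤ 1e-9`), so the walk never proposes moves out of
  the affine hull and fixed exchanges stay exactly fixed.
* **Warmup.** `n_warmup` points from randomized-objective LPs,
  shrunk slightly toward their centroid to keep the chain off the
  boundary.
* **Walk.** Each step picks the direction from a random warmup point
  to the running center, computes the exact chord through the current
  point, and jumps to a uniform point on it. Every `thinning`-th
  accepted point is stored. To suppress floating-point drift, the
  state is re-projected onto the null-space basis every 8192 steps
  inside the kernel. The kernel is numba-compiled; given a seed, the
  stored matrix is bit-reproducible.

Default protocol (`SamplerConfig()`): 1,000 warmup points, 50,000
stored samples, thinning 1,000. The test suite checks 100% sample
feasibility (hard invariant), uniformity on analytic polytopes within
binomial error, and chain mobility (`mean_drift`).

Downstream utilities: `flux_histograms` (bin edges + raw counts per
reaction) and `correlated_sets` (connected components of the
`|Pearson r| ≥ threshold` graph over sampled fluxes, with signed
edges; constant columns, std ≤ 1e-9, are excluded and at least 100
samples are required).

## 4. Cell-line contextualization

`contextualize_cell_line(template, spec, precursors)` runs a fixed
stage order; any stage that breaks feasibility raises a
`ContextualizationError` naming it.

### 4.1 Biomass

`BiomassComposition` holds macromolecule dry-mass fractions (defaults:
protein 0.70, lipid 0.20, RNA 0.08, DNA 0.02, summing to 1) and a
chromosome count. The DNA share is scaled by `chromosomes / 46`
relative to the diploid reference; the freed (or extra) mass is
redistributed to RNA and lipid pro rata, protein held fixed. The
biomass reaction consumes precursor metabolites so that each class's
mass contribution equals its effective fraction, and additionally
hydrolyzes `GAM = 30` mmol ATP per gDW formed (growth-associated
maintenance, a typical mammalian-cell order of magnitude).

### 4.2 Exchange constraints and growth

Each `ExchangeConstraint` sets the exchange bounds to
`rate ± band·|rate|` (rate < 0 for uptake). The biomass flux is fixed
to the fitted growth rate with a relative `growth_band` (default
0.05; pipelines using noisy 5-point growth curves should widen it —
see §6).

### 4.3 Maintenance and oxygen

Non-growth-associated ATP maintenance is a fixed
ATP-hydrolysis reaction at **1.07 mmol/gDW/h** (both bounds). The
oxygen uptake rate is then capped: in the default `fba_max` mode the
cap is the maximal oxygen uptake of the constrained model (so the
model cannot invoke more respiration than its measured exchange
phenotype supports); a `fixed` mode accepts a measured value.

### 4.4 Redox probes

Two optional in-silico probe reactions:

* `PSEUDO_HYPOXIA`: `nad_c + h2_c → nadh_c + h_c` — a
  reducing-pressure probe that converts NAD+ to NADH without touching
  carbon metabolism.
* `NADH_OXIDASE`: `nadh_c + h_c + ½ o2_c → nad_c + h2o_c` — a
  water-forming oxidase that relieves NADH pressure at the cost of
  oxygen.

Both are irreversible, carry no genes, and require their cofactor
metabolites to exist in the template.

### 4.5 Enzymopathy contraction

Mutations arrive as `MutationAnnotation`s with a predicted-deleterious
probability; the damaging threshold is 0.95. A reaction is impaired
iff its GPR evaluates false with all deleterious genes switched off —
an intact isozyme (`or`) rescues the reaction, a broken complex
subunit (`and`) does not. Exchanges and GPR-less reactions are never
contracted.

For each impaired reaction with *unaltered-model* FVA range
`(v_min, v_max)` (computed at `γ = 0` on the model before this
stage), the bounds become

```
literal (default):  [v_min, v_min + 0.25 · |v_min − v_max|]
symmetric:          central 0.25 fraction of the range
```

The literal mode anchors the contracted window at `v_min`; the
symmetric mode is offered for users who prefer a flux-sign-agnostic
contraction. The factor 0.25 is the
`enzymopathy_factor` default and makes the post/pre width ratio
exactly 0.25. Deleterious genes absent from every GPR produce a
warning (mutations in non-metabolic genes are expected), not an
error.

## 5. Rates from culture measurements

* **Growth.** `fit_gompertz` fits
  `N(t) = K · exp(ln(N0/K) · exp(−b t))` by least squares with a
  deterministic initialization; `mu_max = b/e · ln(K/N0)` is the peak
  specific growth rate (1/h).
* **Concentration change.** `core_value` returns the interpolated
  concentration change over a window (mM).
* **Specific rate.** `specific_exchange_rate` converts a
  concentration change into a biomass-specific rate
  `q = ΔC · V / ∫ X(t) dt` (mmol/gDW/h, negative for consumption),
  with `X(t) = N(t) · dry_weight_per_cell` from the Gompertz fit and
  the integral by adaptive quadrature. Default
  `dry_weight_per_cell = 4e-10 gDW/cell`, a standard mammalian-cell
  dry mass of ~400 pg.

## 6. Choosing tolerance bands (error propagation)

Band defaults in the examples and tests are sized *a priori* from
propagating the measurement noise, not tuned to outcomes:

* A 5-point Gompertz fit of a 3-parameter model is intrinsically
  noisy: with multiplicative reading noise of coefficient of
  variation (cv) 0.05 and triplicate-or-better averaging, the
  relative error of `mu_max` is unbiased with median ≈ 0.08 and tail
  up to ≈ 0.36. Hence a growth band of 0.35 and a default of 6
  replicate wells in the synthetic scenarios.
* Endpoint-based rates carry relative error
  ≈ cv · √(C0² + C96²) / |ΔC| / √n. For glucose/lactate the
  concentration change is large (error ≲ 8%, band 0.30); for amino
  acids consumed in small amounts the error reaches ~16%, and because
  *19 such intervals intersect* in the flux polytope, their bands
  must be wide enough that order statistics do not accidentally pinch
  the growth flux — hence a 0.75 band that constrains direction and
  order of magnitude without binding tightly.

## 7. Differential reports

`compare_spans` outer-joins two FVA results per reaction: spans,
`span_ratio = span_b / span_a` (1 when both are zero, ∞ when only the
denominator is), overlap, directionality class
(forward/reverse/bidirectional/blocked at a 1e-9 tolerance) and flip
type. `compare_distributions` computes a per-reaction shift in
[0, 1] between sampled flux distributions (overlap-based by default,
two-sample Kolmogorov–Smirnov optional). `pathway_rollup` aggregates
by subsystem (median span ratio with infinite ratios excluded,
fraction shifted). `build_report` bundles all of it plus correlated
sets into a `DifferentialReport`; `top_shifted(k)` ranks by
distribution shift when samples are attached and by smallest span
ratio otherwise.

## 8. Synthetic data design

`make_toy_network` provides `chain`, `branch`, `cycle`, `simplex` and
seeded `random` networks, each with a truth record (optima, FVA
ranges, free pairs, exchange ids) derived by hand or by construction.

`make_paired_scenario` builds a ~60-reaction core template
(glycolysis to lactate, oxidative route, 19 amino-acid transporters,
nucleotide/lipid synthesis, ATP accounting) plus two `ContextSpec`s:
line A fast (μ = 0.035/h, lactate secretion 1.0 mmol/gDW/h, 44
chromosomes), line B slower (μ = 0.020/h, secretion 0.8) and carrying
two planted deleterious mutations (default LDHA → `LDH_A`, SLC6A7 →
`T_pro_1`) plus benign passengers and one damaging mutation in a
non-metabolic gene that the GPR matching must ignore. Exchange rates
not supplied are derived from the network balance so each planted
phenotype is exactly feasible; the truth record carries the planted
rates, the contracted-reaction list and the analytic oxygen demand.

Two design choices matter for identifiability of planted
enzymopathies:

* **Parallel routes come in threes.** With exactly two parallel
  routes whose summed flux is pinned by exchange constraints,
  contracting one forces the partner's span to mirror it exactly, so
  the planted reaction and its innocent partner are indistinguishable
  by span ratio. Three isozymes/transporters (LDH_A/B/C,
  `T_pro_1/2/3`) leave the unaffected partners a wide joint span, so
  only the contracted reaction shows the 0.25 ratio.
* **Measurable endpoints.** Amino-acid start concentrations (0.2 mM)
  and uptake rates are chosen so that 96-h endpoint changes stay well
  above the multiplicative reading noise.

`make_timecourses` emits Gompertz cell counts (0–96 h, every 24 h)
and metabolite concentration series consistent with the planted rates
(`dC/dt = q · X(t)/V`, integrated by quadrature), with independent
multiplicative noise per reading for each of `n_replicates` wells.
Everything is deterministic per seed.

## 9. Limitations

* The synthetic template is a core network, not a genome-scale
  reconstruction; pathway granularity (one lumped oxidative route,
  lumped syntheses) limits how finely enzymopathies can localize.
* Noise is multiplicative, independent and homoscedastic; real
  assays have correlated plate effects and detection floors.
* The enzymopathy update treats predicted-deleterious variants as a
  hard on/off at probability 0.95 and contracts bounds by a single
  global factor; it does not model partial loss of function per
  variant.
* The oxygen cap in `fba_max` mode inherits any slack in the exchange
  bands; with very wide bands it can exceed the physiological uptake.
* ACHR mixing is validated on low-dimensional polytopes; very
  high-dimensional models may need longer thinning than the default.
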