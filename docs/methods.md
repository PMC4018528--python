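# Methods

## Model and assumptions

The package models cap-dependent translation initiation in the sea urchin
egg as five mass-action reactions over eIF4E, 4E-BP, eIF4G and the two
mutually exclusive complexes eIF4E:4E-BP (inhibited) and eIF4E:eIF4G
(productive), plus an accumulated-protein read-out. Assumptions inherited
from the biology: eIF4E is treated as always mRNA-bound (cap binding is much
tighter than either protein–protein interaction); total eIF4E and eIF4G are
constant on the experimental time scale; 4E-BP is synthesized at a rate
proportional to the productive complex (translation makes the inhibitor) and
degraded only in its free form; protein output is proportional to
[eIF4E:eIF4G], in arbitrary units. No phosphorylation states, calcium
signalling or cell-cycle coupling are represented — fertilization enters
purely as fold changes of rate constants.

Internal units are μM and seconds. Second-order rates quoted in M⁻¹s⁻¹ are
converted at the boundary (9.3×10³ M⁻¹s⁻¹ ≡ 9.3×10⁻³ μM⁻¹s⁻¹); this keeps
all magnitudes far from machine extremes.

## Parameters

| parameter | default | units | origin |
|---|---|---|---|
| k_on1 | 9.3×10⁻³ | μM⁻¹ s⁻¹ | SPR global fit (eIF4E + 4E-BP) |
| k_off1 | 2.2×10⁻⁴ | s⁻¹ | SPR global fit |
| k_on2 | 1.82×10⁻³ | μM⁻¹ s⁻¹ | literature (eIF4E + eIF4G) |
| k_off2 | 2.0×10⁻⁴ | s⁻¹ | literature |
| k_lys_4ebp | 5.9×10⁻⁴ | s⁻¹ | least-squares fit of emetine decay |
| k_cat_4ebp | 3.125×10⁻³ | s⁻¹ | flux balance (see below) |
| k_cat_protein | 1.0 | s⁻¹ (AU) | free scale; protein reported in AU |
| totals | 3.67 / 2.15 / 2.15 | μM | immunoblot densitometry / estimate |

Derived: KD1 = 23.7 nM, KD2 = 109.9 nM. The conventionally printed synthesis
constant is 3.2×10⁻³ s⁻¹; the package defaults to the exact flux-balance
value k_lys·[4E-BP]_free/[eIF4E:eIF4G] = 3.125×10⁻³ s⁻¹ at the unfertilized
partition, so that the unfertilized state is a true fixed point of the ODEs
(the printed number is the rounded report of the same inference; with it,
total 4E-BP would drift ~3% over two hours). Both routes to k_cat —
least-squares flattening of the simulated pool and the closed form — are
implemented and agree to <0.1%.

## Steady states

Two stationary problems arise. The *equilibrium partition* distributes fixed
total pools across free species and complexes given KD1 and KD2; the
*flux-balance steady state* additionally pins free 4E-BP by
k_cat·[eIF4E:eIF4G] = k_lys·[4E-BP], making total 4E-BP an output. Both
reduce to a one-dimensional root find in free eIF4E on (0, total eIF4E): all
other species are closed-form in free eIF4E and the eIF4E-conservation
residual is strictly increasing, so the bracketed root is unique (no
bifurcation analysis is needed). Brent's method with xtol 10⁻¹⁵ μM leaves
equilibrium residuals below 10⁻⁸ relative, enough for fold changes quoted to
3+ significant figures.

Scenario fold changes are reported from the asymptotic flux-balance state
and, where relevant, from finite-horizon trajectories. The fertilization
run essentially reaches its plateau by 30–60 min; the rapamycin run keeps
the slow unfertilized k_off1 and needs ~3 h for the last few percent, so
trajectory-based folds for it are quoted at ≥240 min.

## Integration

`scipy.integrate.solve_ivp` with LSODA and an analytic Jacobian; the fast
binding reactions against slow turnover make the system mildly stiff.
Defaults rtol 10⁻⁸, atol 10⁻¹⁰ μM; grid-search predictions use rtol 10⁻⁶
(verified to change predicted percentages by <10⁻⁵ points). Integration is
split at the ramp boundaries so the solver never steps across a derivative
discontinuity; ramped parameters interpolate linearly in value (not in log)
from t = 0, and the same window applies to all ramped parameters at once.
Species are clipped to zero only for reporting; a species below
−100·atol aborts with an integration error. eIF4E and eIF4G conservation
hold to <10⁻⁶ μM along all tested trajectories.

## Fitting

The objective everywhere is the sum of squared residuals (SSR) between
observed and simulated total 4E-BP, both expressed as percent of their t = 0
value, pooled over replicates (pooling and fitting the replicate mean give
the same argmin, so no per-replicate weighting is used).

* **Emetine fit.** Synthesis is set to zero and SSR is minimized over
  log₁₀ k_lys by bounded scalar minimization (xatol 10⁻⁷ in log units);
  a minimum hugging a search bound raises a warning.
* **Grid searches.** Fold axes are 25 log-spaced nodes per range with the
  canonical folds (1, 8, 16, 32.5) injected so the nominal optimum is
  representable; ramp axes are integer minutes, thinned to ~30 log-spaced
  integers when the range exceeds 30 min (the 1–100 min rapamycin search),
  with 5 and 33 min always present. Because simulating the model is the
  expensive step and is data-independent, predictions for the whole grid are
  computed once (`GridPredictor`) and reused across datasets; a full default
  fertilization grid (≈12k ODE solves) takes about a minute on one core.
  Ties in SSR resolve to the first node in axis order; in practice noisy
  data never tie. Continuous refinement below the grid resolution is
  deliberately not applied: the procedure is exhaustive grid evaluation.
* **Mechanism scans.** The KD1/KD2 ratio is (k_off1·k_on2)/(k_on1·k_off2),
  so an 8-fold shift has four single-parameter routes (k_off1 ×8, k_on2 ×8,
  k_on1 ×1/8, k_off2 ×1/8); these are thermodynamically equivalent but
  kinetically distinct, and the scan scores each against the data. The
  combined scan enumerates all power-of-2 fold 4-tuples with exponents in
  {−5..5} under the exact ×8 constraint (804 tuples; the step density is a
  parameter) and aggregates SSR mean/SD per single-parameter fold value.

## Synthetic data and what it does (not) show

The generator forward-simulates a scenario, samples total 4E-BP at the
experimental grid {0, 5, 10, 15, 20, 30, 45, 60} min, adds i.i.d. Gaussian
noise (default SD 5 percentage points, matching reported experimental SDs of
~5 at the plateau), and renormalizes each replicate to its own noisy t = 0
value, as densitometry normalization does. The renormalization zeroes the
t = 0 residual and adds correlated multiplicative noise (~17% SSR inflation
on the fertilization curve); tests of the noise floor use a Monte-Carlo
expectation of this structure rather than σ². Replicate counts default to
the experimental ones (8–11). Not modelled: blot saturation, loading
variation, heteroscedasticity, inter-animal variability. Passing recovery
tests therefore show the *procedure* is consistent and well-implemented at
realistic noise — not that real densitometry data satisfy the noise model.

**Recovery and identifiability.** On synthetic fertilization data (SD 5,
n = 10) the grid search recovers (×8, ×32.5, 5 min) within one grid step of
the regular search lattice in ~90% of seeded runs; single-dataset argmins
scatter by about one step along the k_off1/k_lys ridge, so the acceptance
script reports the median recovered fold over 31 replicate recovery runs
(the median is within ~3% of the generating folds for every master seed
tried). "One grid step" is measured on the regular log lattice: the injected
canonical folds subdivide it and sit ~3% from regular nodes, which would
otherwise shrink "one step" far below the axis' design resolution of ~21%.
The rapamycin refit is markedly less identifiable: the gentler perturbation
and 33-min ramp leave a nearly flat SSR valley across (fold k_off1,
fold k_lys, ramp), curves along which differ by less than the replicate-mean
noise (~1.6 points), and single-dataset argmins recover (×1, ×16, 33 min)
within one grid step in only ~30–40% of runs. This is a property of the
experiment's information content at this noise level, not of the optimizer
(noiseless rapamycin data recover the generating node exactly).

## SPR kinetics

Sensorgrams follow closed-form 1:1 Langmuir kinetics (association
R_eq(1−e^(−(k_onC+k_off)t)) with R_eq = R_max·C/(KD+C); exponential
dissociation), verified against direct ODE integration to 10⁻⁹ of R_max.
The global fit shares k_on, k_off and R_max across the dilution series
(3-fold steps from 4.37 μM to 53.9 nM) and runs Levenberg–Marquardt in log
space for positivity, with asymptotic standard errors via the delta method
and an ill-conditioning guard on JᵀJ. Phase boundaries come from the
sensorgram record (the instrument defines them); baseline referencing and
mass transport are out of scope — synthetic curves are generated
pre-referenced, 300 s per phase, R_max 60 μRIU by default. At 1% noise the
fit recovers both rates with <1% bias and <5% scatter; KD from kinetics
matches KD from an equilibrium saturation fit within 2% on noiseless,
fully equilibrated series.

## Problem sizes and runtimes

Defaults were chosen so the full analysis is interactive on one core:
scenario simulations and steady states are sub-second; a default
fertilization grid search is ~1 min (predictions cached for multi-dataset
studies); the emetine and SPR fits are seconds; recovery studies reuse one
cached grid across all seeds. The acceptance script completes in ~2 min.

## Known limitations

* Single steady state by construction; no multistability, stochasticity or
  spatial effects.
* k_cat_protein is unidentifiable from relative protein data; protein is
  reported in arbitrary units (normalizable to the 60-min unfertilized
  value).
* The rapamycin parameter set is reported as the canonical (×1, ×16,
  33 min) configuration; as noted above, time-course data of realistic
  quality cannot pin it down uniquely.
* The emetine condition is modelled as an instantaneous k_cat_4ebp = 0 at
  t = 0 (the drug blocks all synthesis); drug uptake kinetics are ignored.
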