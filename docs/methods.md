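# Methods

## Scope and state variables

The package models two-step denitrification in a well-mixed anoxic batch
system. Twelve states are integrated (units in brackets):

| state | meaning |
| --- | --- |
| xDOC, xDIC [mM] | dissolved organic / inorganic carbon (CH₂O, CO₂) |
| xNO3, xNO2, xN2 [mM] | nitrate, nitrite, dinitrogen |
| xBM [mM] | community biomass, elemental formula C₅H₇O₂N |
| ρ₁, ρ₂ [–] | lumped internal-resource pools (ATP, NADH, polymerases, ribosomes, genes) |
| τ₁, τ₂ [–] | transcript pools |
| e₁, e₂ [pmol/g soil] | functional enzyme pools (pathway 1: nitrate-reductase class NarG/NapA; pathway 2: nitrous-oxide-reductase class NosZ) |

Pathway 1 reduces NO₃⁻ to NO₂⁻; pathway 2 lumps the remaining chain
NO₂⁻ → NO → N₂O → N₂ into one reaction tracked by the terminal (NosZ-class)
enzyme. NO and N₂O are treated as fast intermediates and are not state
variables; NH₄⁺ is assumed non-limiting; the dissimilatory
nitrate-to-ammonium branch is excluded. H⁺ and H₂O are not bookkept — the
model closes only the carbon and nitrogen balances.

## Stoichiometry

Per mole of DOC routed through pathway *i*, a fraction f_i is respired and
(1−f_i)/5 appears as biomass carbon:

* pathway 1: DOC + 2f₁ NO₃⁻ → 2f₁ NO₂⁻ + f₁ DIC + (1−f₁)/5 BM
* pathway 2: DOC + 4/3 f₂ NO₂⁻ → 2/3 f₂ N₂ + f₂ DIC + (1−f₂)/5 BM

The N₂ coefficient is fixed at (2/3)f₂ by nitrogen conservation: 4/3 f₂
moles of NO₂-nitrogen must appear as 2·(2/3 f₂) moles of N₂-nitrogen.
(Alternative typesettings of this coefficient circulate; element balance is
non-negotiable, and the implementation enforces dNO₃+dNO₂+2·dN₂ = 0
identically.) Biomass decays at k_deg, returning 5 carbons to DOC per BM,
which closes the carbon balance dDOC+dDIC+5·dBM = 0 identically. Both
identities are tested at machine precision on random states.

## Kinetics and regulation

Unregulated uptake rates are dual-substrate Monod products,
rᵢᵏⁱⁿ = kᵢ·DOC/(K_d,i+DOC)·Aᵢ/(K_a,i+Aᵢ); the realised rate is gated by the
enzyme pool, rᵢ = eᵢ·rᵢᵏⁱⁿ, so k_i carries units mM·(g soil/pmol)/d and rᵢ
comes out in mM/d. Resource synthesis r_R,i mirrors the uptake Monod product
(no enzyme factor) scaled by k_R,i; transcription r_T,i = k_T,i·ρᵢ/(K_T+ρᵢ);
translation r_E,i = k_E,i · τᵢ/(K_E+τᵢ) · ρᵢ/(K_E+ρᵢ). The single published
half-saturation constant K_E = 0.25 is applied to both translation factors.

Resource balances receive a constitutive term α_R,i plus an inductive term
u_i·r_R,i under cybernetic control; transcripts and enzymes have plain
synthesis/degradation balances. The matching law u_i = p_i/Σp_j allocates
inductive synthesis in proportion to return-on-investment, with p_i taken as
the carbon uptake rate r_i. Degenerate denominators are defined by their
continuous limits: when p₁+p₂ = 0, u₁ = u₂ = 0 (only constitutive synthesis
persists — this is what holds enzyme levels at a base line long after
substrate depletion); when r₁+r₂ = 0 the instantaneous biomass yield
(Y₁r₁+Y₂r₂)/(r₁+r₂), Y_i = (1−f_i)/5, is defined as 0. No ε-regularisation
is introduced.

Post-translational activity control is deliberately absent: enzyme activity
is proportional to enzyme concentration.

## Default parameters and initial condition

The packaged defaults are the published point estimates for the
hyporheic-zone sediment batch experiment:

f₁ = 0.56, f₂ = 0.99; k₁ = 6.23, k₂ = 5.71 mM·(g soil/pmol)/d;
K_d = 0.25 mM (both pathways); K_a,1 = 0.001, K_a,2 = 0.004 mM;
k_deg = 0.11 /d; k_R = (2.84, 1.03), k_T = (0.13, 0.25),
k_E = (1.84, 1.56) /d; K_T = K_E = 0.25; α_R = 0.2 /d and all degradation
constants β = 0.8 /d. Initial condition: DOC 61.1, NO₃⁻ 18.3, NO₂⁻ 0,
N₂ 0, DIC 1, BM 1.5 mM; all six regulatory pools start at 0.001.

Validation allows rate constants to be zero (limiting cases used by the
tests: switched-off synthesis, no biomass decay) but requires
half-saturation constants, which sit in denominators, to be strictly
positive, and f_i ∈ [0, 1].

## Numerical integration

The system is stiff once nitrate crashes (µM-scale half-saturations against
mM-scale pools), so `simulate` uses LSODA with rtol 1e−8 / atol 1e−10 and
samples a uniform grid, default 0.01 d over 20 d — fine enough to resolve
peak times well below the 0.1-d resolution lags are reported at. Inside the
right-hand side, Monod factors are evaluated on states clipped at zero so
O(atol) negative excursions from adaptive stepping cannot create negative
rates; trajectory outputs are reported unclipped, and a run is rejected if
any state falls below −10·atol. Derived series (r₁, r₂, u₁, u₂, yield) are
recomputed from the grid states, not taken from solver internals, so they
are solver-agnostic.

Correctness of the integration is cross-checked against an independently
coded fixed-step classical RK4 integrator at Δt = 1e−4 d; agreement is
required to 1e−5 relative with an absolute term of 1e−9 (10× the solver
atol, which is where "zero" lives for a decayed concentration — a bare
ratio on a 1e−11 mM tail would compare solver noise against solver noise).
Observed agreement is ~2e−9 relative on meaningful states. Conservation
drift over the default run is ~1e−12 mM against a 1e−6 mM budget.

## Lag and depletion analysis

The regulatory delay between two cascade stages is defined as the difference
of the times of their global maxima on the simulation grid, ties broken to
the earliest time. The lag table keeps grid-resolution values (so
lag_RE = lag_RT + lag_TE holds exactly) and rounds to 0.1 d only in reports,
matching the precision at which such lags are quoted. A series whose maximum
sits on the final grid point is rejected as inconclusive rather than
reported.

Depletion time is the first time after a series' maximum that it falls below
a threshold fraction (default 1%, insensitive over 0.5–2%) of a reference —
the initial value for species present at t = 0, the maximum for transient
species — with linear interpolation between grid points; a never-crossed
threshold returns an infinite sentinel. Phase-diagram correlations remove
the cascade delay by shifting the downstream series earlier by the
peak-time lag (the only delay definition the model analysis uses), truncating
to the overlap, and computing a Pearson coefficient; overlaps under 10
points are rejected.

## Calibration

The fittable set is {k₁, k₂, k_R,1, k_R,2, k_T,1, k_T,2, k_E,1, k_E,2,
k_deg, f₁}: the parameters identifiable from a single batch experiment.
Half-saturation constants, α's, β's and f₂ stay fixed. Residuals are
(model − observed mean) per (time, observable), normalised by the maximum
observed mean of that observable so the mM-scale nutrients and pmol-scale
enzymes are commensurate (SD-weighting is available as an option).
Optimisation is bounded trust-region least squares (`scipy`'s TRF), default
bounds [1e−3, 100] (f₁: [0.01, 0.999]), starting at the fixed parameter
values unless told otherwise, with an optional seeded multi-start. Trial
simulations that blow up in stiff corners return penalty residuals (10× the
largest clean residual seen) instead of aborting the search. Calibration
simulations run at rtol 1e−6 / atol 1e−8, evaluated directly at the
observation times; on noise-free synthetic data the fit recovers all ten
parameters to well under 1% from a 1.5× perturbed start, so the looser
tolerance costs no recoverable accuracy.

Confidence intervals follow a resampling recipe: each of n_sets synthetic
datasets draws every (time, observable) value uniformly from
[mean − SD, mean + SD]; each is refitted (started at the point estimates);
parameter sets with any value outside the per-parameter 2.5–97.5%
linear-interpolation quantile band are removed; the min/max of each
parameter over the retained sets are the 95% limits. Resample *j* uses an
independent RNG substream keyed (seed, j), so any subset of resamples is
reproducible in isolation. Two properties of this recipe are worth knowing:
the uniform ±SD draw is tail-bounded (about 1.5 standard errors of a
replicate mean), and the trim-then-min/max step cannot widen the interval —
so for a sloppy multi-parameter fit the intervals tend to be *narrower*
than the frequentist sampling spread of the estimates, and joint coverage
over all ten parameters is substantially below the per-parameter level.
The test suite measures exactly this on synthetic data; treat the intervals
as an uncertainty summary of the published procedure, not as calibrated
simultaneous coverage.

## Synthetic data generator

The generator emulates the batch experiment's measurement design: default
sampling daily from day 0 to day 20; nutrient observables (DOC, DIC, NO₃⁻,
NO₂⁻) in 3 replicates; each enzyme observable in 2 effective replicates
(standing in for the average of two signature peptides measured twice).
Replicates are truth × (1 + ε), ε ~ N(0, scale) truncated at −1, with a 5%
default scale; noise is multiplicative because the observables span three
orders of magnitude, and an additive variant is available. Truth values are
taken from a tight-tolerance simulation and clipped at zero.

What the generator does *not* emulate: the proteomics pipeline (digestion
efficiency, peptide recovery), instrument-specific error structure,
detection limits, or any correlation between replicates. Passing
calibration tests on this generator therefore demonstrates that the
estimation machinery is self-consistent under the stated noise model — not
that the model is identifiable from any particular real assay.

## Problem sizes used by the test suite

The default simulation (2001 grid points, 20 d) backs all deterministic
checks. The RK4 cross-check uses 200,000 fixed steps. Calibration tests use
the 21-day-point design; the resampling-CI smoke test uses 50 resamples,
a deliberately small bootstrap that exercises the full recipe while keeping
the suite fast — the recipe itself defaults to 500 resamples.

## Known limitations

* Two lumped reactions only; no explicit NO/N₂O dynamics, so transient
  accumulation of those intermediates is invisible.
* Enzyme "concentration" is a community-pooled quantity; the model carries
  no information about which organisms express what.
* The regulation cascade is phenomenological: ρ, τ are dimensionless pools,
  and rate constants for them are only indirectly identified through
  nutrient and enzyme fits.
* The resampling CI recipe under-covers for this model (see Calibration);
  widths should be read comparatively, not as exact 95% intervals.
* Exact reproduction of the published parameter estimates is not possible
  from this package alone: the original experimental time series is not
  deposited in machine-readable form, so calibration is demonstrated on
  synthetic data.
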