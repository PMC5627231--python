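# rscm — regulation-structured cybernetic model of denitrification

`rscm` simulates the coupled nutrient and gene-regulation dynamics of
microbial denitrification in an anoxic sediment batch reactor, and explains a
phenomenon that plain Monod models cannot: functional enzymes keep being
synthesised for days *after* their substrate is gone, so enzyme concentrations
peak long after reaction rates do.

It is aimed at biogeochemical and microbial-ecology modellers who need a
trait-based community model in which the traits are pooled **functional
enzymes** (not species or guilds), with metabolic regulation represented
mechanistically through transcription and translation.

## The model

Denitrification is lumped into two reactions sharing dissolved organic carbon
(DOC, modelled as CH₂O) as electron donor, with energy fractions f₁, f₂ and
biomass C₅H₇O₂N:

    DOC + 2f₁ NO₃⁻   →  2f₁ NO₂⁻ + f₁ DIC + (1−f₁)/5 BM
    DOC + 4/3 f₂ NO₂⁻ →  2/3 f₂ N₂ + f₂ DIC + (1−f₂)/5 BM

Biomass decays at rate k_deg back into DOC (5 carbons per BM). Each pathway
*i* carries a regulation cascade with three pools — internal resources ρᵢ
(ATP, polymerases, ribosomes, …), transcripts τᵢ, and enzymes eᵢ:

    dρᵢ/dt = α_{R,i} + uᵢ·r_{R,i} − β_{R,i}·ρᵢ
    dτᵢ/dt = r_{T,i} − β_{T,i}·τᵢ
    deᵢ/dt = r_{E,i} − β_{E,i}·eᵢ

Carbon uptake is enzyme-regulated Monod kinetics, rᵢ = eᵢ·rᵢᵏⁱⁿ with
rᵢᵏⁱⁿ = kᵢ · DOC/(K_d+DOC) · Aᵢ/(K_a+Aᵢ) for acceptor Aᵢ. Inductive resource
synthesis is allocated by the cybernetic **matching law**
uᵢ = pᵢ/(p₁+p₂) with return-on-investment pᵢ = rᵢ, so the community invests
its regulatory machinery in proportion to what each pathway currently earns.
Twelve states are integrated: six nutrient/biomass concentrations and the six
regulatory pools. Two exact invariants hold: d(DOC+DIC+5·BM)/dt = 0 and
d(NO₃+NO₂+2·N₂)/dt = 0.

The package ships the published parameter set and the batch initial condition
(61.1 mM DOC, 18.3 mM NO₃⁻) as defaults, plus modules for peak-time lag
analysis, least-squares calibration with resampling confidence intervals, and
a synthetic-data generator that mimics the experiment's replication design.

## Worked example

```python
from rscm import simulate, lag_table, depletion_time, conservation_report

traj = simulate()                      # packaged defaults: 20 d batch, 0.01 d grid
table = lag_table(traj)
print(f"pathway 1 (NO3- -> NO2-): resource->transcript {table.lag_RT1:.1f} d, "
      f"transcript->enzyme {table.lag_TE1:.1f} d, total {table.lag_RE1:.1f} d")
print(f"pathway 2 (NO2- -> N2):   resource->transcript {table.lag_RT2:.1f} d, "
      f"transcript->enzyme {table.lag_TE2:.1f} d, total {table.lag_RE2:.1f} d")
no2 = depletion_time(traj.times, traj.series("xNO2"), 0.01, "max")
no3 = depletion_time(traj.times, traj.series("xNO3"), 0.01, "initial")
print(f"NO3- below 1% of initial at {no3:.2f} d; NO2- exhausted at {no2:.2f} d")
c, n = conservation_report(traj)
print(f"carbon/nitrogen conservation drift: {c:.1e} / {n:.1e} mM")
```

prints

```
pathway 1 (NO3- -> NO2-): resource->transcript 3.0 d, transcript->enzyme 0.3 d, total 3.3 d
pathway 2 (NO2- -> N2):   resource->transcript 0.5 d, transcript->enzyme 0.2 d, total 0.8 d
NO3- below 1% of initial at 5.72 d; NO2- exhausted at 6.76 d
carbon/nitrogen conservation drift: 6.7e-13 / 3.4e-13 mM
```

Reading: the nitrate pathway's enzyme pool peaks 3.3 days after its resource
pool — transcription, not translation, is the slow step — while the nitrite
pathway responds within a day. Nitrate is effectively exhausted by day 5.7
and nitrite by day 6.8; both element balances are conserved to solver
precision.

The same workflow is available from the shell:

```sh
rscm simulate --out traj.tsv
rscm lags --traj traj.tsv --out lags.tsv
rscm synth --noise 0.05 --seed 0 --out obs.tsv
rscm fit --data obs.tsv --free k1,k2,f1 --out fit.txt
rscm bootstrap --data obs.tsv --n-sets 500 --seed 0 --out ci.txt
```

## Layout

| module | contents |
| --- | --- |
| `rscm.core` | parameter/state types, Monod kinetics, matching law, ODE right-hand side |
| `rscm.simulate` | stiff adaptive integration, trajectories, conservation checks, IO |
| `rscm.lags` | peak times, lag tables, depletion times, lag-aligned correlations |
| `rscm.calibrate` | observation sets, weighted residuals, bounded least squares, resampling CIs |
| `rscm.synth` | synthetic observation generator with the batch replication design |
| `rscm.cli` | `rscm` command-line entry point |

See `docs/methods.md` for the full model description, parameter meanings,
numerical choices and known limitations.
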