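# Methods

`bsfdeb` models the growth and metabolic performance of black soldier fly
(BSF, *Hermetia illucens*) larvae and connects two views of feed
efficiency: the *net growth efficiency* (NGE), a purely metabolic quantity,
and the *mass-balance indicators* (BR, SCE, SCR, SRR) measured in rearing
experiments. All internal model state is carried in carbon equivalents
(mg C), assuming feed, tissue and lipid share an average elemental
composition; dry-weight observables are obtained through a single carbon
fraction `f_C`. Every efficiency ratio is therefore invariant to the exact
value of `f_C`.

## Kinetic model (logistic + growth/maintenance respiration)

Larval mass follows Verhulst's logistic equation,
`dX/dt = mu X (1 - X/Xmax)`, which closely resembles measured BSF growth
curves: near-exponential growth at specific rate `mu` through the first
half of the lifespan, then slowing to the asymptote `Xmax`. Respiration is
partitioned Pirt-style into a growth-associated and a maintenance term,
`r_CO2 = Y r_X + m X`, the same structure as the classical
growth-associated product model for microbial cultures. Assimilation is
the sum `r_A = r_X + r_CO2`; with `m = 0` the instantaneous NGE is the
constant `1/(1+Y)`.

`Y` is a **cost** ratio — mg C respired per mg C incorporated — not a
yield fraction. Only this reading is consistent with the package's
calibration: with `Y = 0.44` the maintenance-free growth yield is
`1/1.44 ≈ 0.69`, leaving room for the simulated lifetime efficiencies of
0.53–0.58; a yield reading would cap them at 0.44.

Fitting (`fit_verhulst`) is bounded nonlinear least squares with 8 seeded
multistarts; bounds `mu ∈ (0, 3]`, `Xmax ∈ (max(X), 10 max(X)]`. Constant
series are reported as degenerate rather than fitted.

## Dynamic two-compartment energy budget

The dynamic model resolves the larva into structural biomass `B` and
storage lipid `L` and is driven by two rate-limiting flows, both declining
logistically in the relative weight `x = X/Xmax`:

* specific feed assimilation `a(x) = a_max / (1 + exp(k_A (x - x_A)))`,
  maximal in hatchlings and effectively zero in the prepupa;
* specific structural growth, capped at `s_max` and declining only after
  the final-instar midpoint `x5`:
  `demand = s_max B / (1 + exp(k_B (x - x5)))`.

Assimilated carbon is allocated maintenance-first (`m X`), then structural
synthesis at cost `Y` up to the demand, and any excess overflows to lipid
at cost `Y_L` — lipid being more reduced than feed, its synthesis releases
CO₂ to keep the redox balance neutral. `Y_L = 0.38` comes from an electron
balance: converting feed of degree of reduction ≈ 4.2 into lipid of ≈ 5.8
releases `5.8/4.2 - 1 ≈ 0.38` C as CO₂ per C stored. If supply falls below
maintenance, growth stops and the deficit is drawn from lipid (starvation
flag). The flux partition closes carbon exactly by construction, and the
cumulative assimilation and CO₂ are co-integrated as ODE states so the
trajectory-level balance closes to integrator precision (measured
≤ 1e-14 relative over random parameter draws).

**Prepupation** fires when the specific assimilation rate collapses to the
maintenance level, `a(x) ≤ m + 0.01 a_max`. A pure `a(x) ≤ 0.01 a_max`
threshold is unreachable whenever `m > 0.01 a_max`: weight gain stalls
exactly where `a(x) = m`, which the trajectory approaches only
asymptotically. The margin keeps the event finite-time for all parameter
values; a hard cap at `X = 1.05 Xmax` covers the maintenance-free limit
where `a(x) = m` never happens. After the event, the animal stops feeding
and pays maintenance from lipid; this phase has the exact solution
`X(t) = X_pp e^{-m(t - t_pp)}` with `B` constant, which is used directly
(no integrator), terminating at lipid exhaustion.

Larval-phase integration uses LSODA with `rtol 1e-8`, `atol 1e-10` and
event location by the solver's root finder; a dt = 1e-4 explicit-Euler
brute force agrees with it to ≤ 3e-4 maximum relative deviation in weight.

### Default parameters

| symbol | value | meaning |
|---|---|---|
| `a_max` | 1.2 /d | maximal specific assimilation rate (chicken feed) |
| `Y` | 0.44 | cost of growth, C respired per C into structure |
| `m` | 0.08 /d | maintenance coefficient |
| `s_max` | 0.8 /d | maximal specific structural growth rate |
| `x5`, `k_B` | 0.6, 12 | midpoint/steepness of the structural decline |
| `x_A`, `k_A` | 0.78, 10 | midpoint/steepness of the assimilation decline |
| `Y_L` | 0.38 | cost of lipid synthesis (redox CO₂) |
| `f_C` | 0.49 | carbon fraction of dry weight |
| `h` | 2.33 | water bound per unit structural dry mass |

`a_max`, `Y`, `m` are the fitted, feed-dependent constants. The remaining
shape constants are reconstruction choices: the two logistic declines are
only qualitatively constrained (early specific growth near-constant,
assimilation vanishing at the maximal weight), so their midpoints and
steepnesses were set once so that the chicken-feed scenario reproduces the
known biology — prepupation close to `Xmax` at t ≈ 12 d from a 0.2%-of-final
start weight, prepupal lipid fraction ≈ 0.37 of dry weight, dry-matter
content rising from 0.30 to ≈ 0.40, and a lifetime NGE*_avg ≈ 0.55, inside
the 0.53–0.58 band reported for chicken feed. `s_max` sits just above the
supply-limited early specific growth rate `(a_max - m)/(1+Y) ≈ 0.78`, so
early growth is supply-limited (no lipid) and lipid accrues mainly late,
matching the observed late rise of relative lipid content. `h` gives the
lean-larva dry-matter content `1/(1+h) ≈ 0.30`; lipid is treated as
anhydrous, so fattening raises dry-matter content — which is what makes
dry-matter content usable as the out-of-fit coherence observable.
Maintenance scales with total mass `X` (not `B` alone), consistent with the
whole shrinking animal paying maintenance in the prepupa; prepupal
maintenance uses the larval `m`. Young larvae start lean (`L0 = 0`,
configurable).

## Efficiency measures

Instantaneous `NGE = r_X / r_A` with `r_X = r_B + r_L`; lifetime
`NGE*_avg = (X - X0) / A` in carbon equivalents (the asterisk marks the
variable-composition model, in which carbon and energy are not conserved
with the same efficiency). Useful exact properties, all covered by tests:
`NGE*_avg = 1/(1+Y)` when `m = 0` and growth is demand-unconstrained;
`NGE*_avg ≤ max(1/(1+Y), 1/(1+Y_L))` always; it falls monotonically with
`m` and with harvest delay past prepupation; and it is invariant to `Xmax`
scaling at fixed `X0/Xmax` because all specific rates depend on `x` only.

The mass-balance indicators follow the standard ledger definitions
(`BR = ΔX_DW/W_DW0`, `SCE = ΔX_DW/(-ΔW_DW)`, `SCR = 1/SCE`,
`SRR = -ΔW_DW/W_DW0`) and satisfy `BR = SCE·SRR` identically.
`complete_indicators` fills missing literature cells from these
identities, marks them `derived-from-identity`, and flags disagreement
between independent routes beyond 0.02 absolute (the resolution of
2-decimal published values). NGE values outside (0, 1) are reported with a
warning, never clamped — they are diagnostic (e.g. harvest deep in the
prepupal phase). Dry-weight-based indicators and carbon-based NGE are
never mixed; both rest on the shared `f_C` when compared.

## Synthetic data

The generator emulates the structure of published rearing studies.
Observation series: simulate, predict observables, then apply
multiplicative lognormal noise (CV `cv_weight`, mean-one) to dry weight
and lipid and additive Gaussian noise to the CO₂ rate; every draw is a
pure function of (parameters, seed). Default sampling is every 2 days
until 4 days past prepupation.

Rearing experiments couple `n_larvae` identical average larvae to a
substrate pool `dW/dt = -n r_A/(AD f_C) - mu_mic W`: larvae ingest
`1/AD` times what they assimilate (digestion efficiency `AD`, undigested
ingesta returning to the residue as frass), and microbes consume remaining
substrate at first-order rate `mu_mic` (fully respired; no microbial
growth dynamics — the term is a lumped knob, not a microbiome model).
Defaults (100 larvae, 40 g substrate, `AD = 0.8`, `mu_mic = 0.02`/d) put
the microbial share of substrate removal near 40% and the resulting SCE at
≈ 0.34, inside the 0.14–0.48 band observed across chicken-feed studies.
The ledger closes exactly (supplied = remaining + ingested + microbial)
and is returned noise-free: end-point bulk weighings are far more precise
than per-larva series, and a noisy ledger would blur the ordering
`SCE ≤ NGE*_avg` that the generator exists to demonstrate. Note that with
frass counted in the residue — as harvest-time mass balances do — `AD`
cancels out of SCE, so SCE equals NGE*_avg exactly when `mu_mic = 0` and
sits strictly below it otherwise.

What passing tests on these data do **not** show about real rearing:
molting pauses in intake and growth, cohort variability and mortality,
temperature/density effects, substrate-composition effects and microbial
growth dynamics are all outside the model, so real fits should expect
systematic residuals (e.g. around the ~20%-of-final-weight molt) that the
synthetic benchmark cannot produce.

## Fitting and identifiability

`fit_deb` minimises scale-free weighted least squares (each observable's
residuals divided by its series mean) over seeded Latin-hypercube
multistarts (default 12) with bounded trust-region least squares; default
free parameters `a_max ∈ [0.5, 3]`, `Y ∈ [0.1, 1]`, `m ∈ [0.01, 0.3]`,
with `Xmax`/`X0` optionally freed. During fitting the simulator runs at
`rtol 1e-6` evaluated only at observation times; predictions are extended
constant past an early (lipid-depleted) trajectory end for robustness.
Non-convergence is flagged with the full multistart table.

Dry weight alone leaves `Y` and `m` weakly identifiable — multistart
dispersion of `m` above 50% on the default benchmark — because cost and
maintenance trade off against `a_max` in the growth curve. Adding the CO₂
(or lipid) series collapses that dispersion several-fold; this is the
computational argument for measuring CO₂ production alongside weight.
`recovery_experiment` (20 replicates, 5% weight noise, CO₂ observed)
recovers all three parameters with median absolute relative errors of
1–4%.

## Problem sizes and numerical choices

Default analyses use one average larva per cohort, trajectories of ~900
grid points (output step 0.02 d), 50-draw conservation sweeps, 20-replicate
recovery studies and 12-start fits; these sizes make the full validation
suite run in a few minutes while leaving all conclusions
resolution-independent (halving the output step or doubling replicates
changes no reported digit at the stated precision). Ties and degenerate
inputs are handled explicitly: zero-assimilation windows raise an
undefined-ratio error rather than returning 0, constant series are
degenerate fits, indicator denominators of zero mark the affected
indicators undefined, and sub-maintenance supply sets the starvation flag.

## Known limitations

The two logistic decline shapes are reconstructions constrained by
qualitative behaviour, not by printed equations; refitting their four
shape constants to raw multi-study data would be the natural next step.
The prepupation margin (1% of `a_max` above maintenance) is a modelling
convention and an influential one: halving (doubling) it delays (advances)
`t_pp` by about one day and moves NGE*_avg by roughly ∓0.026 on the
chicken-feed scenario — about the width of the 0.53–0.58 band reported
across chicken-feed datasets.
The microbial term is first-order with unit CO₂ yield — a placeholder for
competition, not an estimate. Wet weight enters only through the static
hydration constant `h`.
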