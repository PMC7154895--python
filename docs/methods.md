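# Methods

## The model

`loliumsim` simulates the year-to-year dynamics of an Italian ryegrass
(*Lolium multiflorum*) population through its soil seed bank, for a
glyphosate-susceptible and a glyphosate-resistant biotype. The persistent
state variable is the seed-bank density SB (seeds m⁻²); everything else is
recomputed within each year.

**Emergence.** Seedling emergence is driven by soil thermal time. Daily mean
soil temperature is predicted from air temperature by a linear regression
(`T_soil = 0.84·T_air + 3.81`); degree days above the base temperature
T_base = 1.9 °C accumulate from March 10 (the start day contributes its own
degree days). Cumulative percent emergence follows a Gompertz curve of
thermal time TT,

    y(TT) = 100 · exp(−exp(−k (TT − TT₀))),   k = 0.0151 °Cd⁻¹, TT₀ = 444.20 °Cd.

Days colder than T_base contribute zero degree days (clipped, the standard
degree-day convention), so TT never decreases.

**Cohorts.** The season's emergence y(TT) is split into three cohorts at
three boundary dates (defaults March 31, April 30, June 30; May emergence is
assigned to the third cohort). The cohort allocations are the increments of
the cumulative curve at those dates, renormalized by default so that the
whole emerged pool SB·e is allocated; a switch keeps the raw increments and
treats the residual as fatal germination. Boundaries are configuration, not
constants.

**Annual life cycle.** With the year's realized parameters:

    SDL   = SB · e
    SDL_i = fraction_i · SDL
    AP_i  = SDL_i · sdls_i · (1 − rc_i)
    SP_i  = f (1 − fr_i)(1 − lp)(1 − rc_i) / (1 + b · AP_i)
    TSP_i = SP_i · AP_i · (1 − l)
    SB'   = SB (1 − e)(1 − sm) + (Σ_i TSP_i)(1 − cr)

Per-plant seed production is density dependent (hyperbolic), halving at
density 1/b; each cohort's density term uses only its own AP_i, as the model
is written — a deliberate fidelity choice even though shared competition
would be ecologically more usual. The herbicide kill rate rc of a cohort's
action appears in both the survival and the fecundity equation as printed;
because survivors of a late application arguably still reproduce, the
`rc_applies` switch (`both` | `survival_only` | `fecundity_only`, default
`both`) restricts where rc acts. Under the default, the strongest chemical
programmes (e.g. late + late + early) are driven extinct deterministically;
with `survival_only` they settle at a low but positive equilibrium.
Densities are continuous; seed banks below 10⁻⁶ seeds m⁻² (configurable)
are reported as 0 to avoid denormal drift.

**Management strategies.** Ten packaged strategies: M1 no control; M2–M4
fixed per-cohort chemical programmes repeated every year (early
post-emergence kill rate 0.98 on young plants, late 0.91 on adults); M5–M10
crop-rotation cycles (wheat/soybean 0.89, oat/soybean 0.48, oat/corn 0.89)
that discount the year's seed return and repeat cyclically over the horizon.
Chemical strategies use cr = 0 and rotations rc = 0 — the rotation
coefficients already embody in-crop weed control. The source material
describes M4 three inconsistent ways; the packaged default is late C2 +
late C3 and the other two variants are selectable (`model.m4_variant`).

**Stochasticity.** Each rate parameter with a published spread is drawn
yearly from a beta distribution whose shapes come from method-of-moments
inversion of its mean and sd (a = μν, b = (1−μ)ν, ν = μ(1−μ)/σ² − 1);
infeasible moments (σ² ≥ μ(1−μ)) raise an error rather than being clamped.
Maximum fecundity f is normal, rejection-truncated at zero (negligible at
the packaged means). Seed mortality sm (0.49) and seed losses l (0.19) are
fixed. The area parameter b (0.17 ± 0.03 susceptible, 0.12 ± 0.03
resistant) is sampled with the beta machinery since 0 < b < 1 — a modelling
convention, as b is an area, not a probability. One independent draw per
parameter per replicate-year represents uncorrelated environmental
variation; no correlation structure is imposed because none is published.

**Reproducibility.** Every random draw comes from a
`numpy.random.SeedSequence([master_seed, replicate, year, stream])`
substream (stream 0: climate noise, stream 1: parameter draws), so adding
replicates or years never perturbs earlier ones and any replicate is
exactly reproducible from its indices.

## Synthetic climatology

No daily weather record is packaged; the generator emulates one as a cosine
annual cycle plus independent Gaussian daily noise:

    E[T(d)] = annual_mean + annual_amplitude · cos(2π (doy(d) − warmest_day)/365.25)

Defaults: annual_mean 13.5 °C, amplitude 5.5 °C, warmest day 15 (southern-
hemisphere phase: warm January, cooling through the March–June emergence
season), noise sd 2.0 °C, all configurable. The mean is calibrated so that,
with the fixed emergence constants above, the noise-free emergence flow
spreads over the three cohort windows the way the three-cohort life cycle
describes — a small March flush (~0.6 %), the bulk in April (~98 %), a
trace into June (~1 %) — and so that a +2.5 °C offset advances the flow
into the first cohort. This matters: the warming response of the
uncontrolled equilibrium changes sign with the site mean (warmer defaults
complete emergence before May and invert the effect), so the annual mean is
the one climatology parameter that should be set thoughtfully for a new
site. A value of 13.5 °C corresponds to the cool highland fringe of the
ryegrass-growing region rather than a warm lowland site.

What the generator does *not* emulate: autocorrelated synoptic weather,
precipitation or soil-moisture control of germination, CO₂ effects, trends.
Passing tests therefore show internal consistency of the model and the
direction of temperature effects, not skill against observed field
dynamics. Users with a real record can supply it as a
`date,tmean_air_c` CSV (`simulate --temperature-csv`), which replaces the
synthetic climatology (the scenario offset still applies).

Climate scenarios are additive offsets: scenario 1 is +0.0 °C, scenario 2
+2.5 °C (the projected mid-century warming for the region). In
deterministic runs the climate noise is forced to zero along with all
parameter spreads.

## Deterministic oracles

Two analytic companions verify the stochastic engine:

- **Low-density growth factor** λ: linearization of the annual map at
  SB → 0,
  λ = (1−e)(1−sm) + e(1−cr)(1−l) Σ_i frac_i·sdls_i·(1−rc_i)·f(1−fr_i)(1−lp)(1−rc_i).
  The population invades iff λ > 1 (for rotation cycles, iff the product of
  yearly factors exceeds 1).
- **Fixed-point equilibrium**: the annual map is monotone and saturating,
  so its positive fixed point (when λ > 1) is unique; it is found by
  bisection of g(SB) − SB on [0, cap] with cap the closed-form saturation
  bound Σ_i f(1−fr_i)(1−lp)(1−l)/b / (1 − (1−e)(1−sm)) + 1, to 10⁻⁸
  relative tolerance (200-iteration hard limit). Rotation cycles are
  composed into a single multi-year map; the fixed point is the
  start-of-cycle state and a `phase` argument forward-iterates it for
  comparison with horizons that are not cycle multiples. Forward iteration
  of the map for 200 years agrees with the bisection root to better than
  10⁻⁶ relative for every packaged strategy and population.

## Reported statistics and problem sizes

A standard run is 10 years × 100 replicates from an initial bank of
2000 seeds m⁻², and the reported "equilibrium" is the mean ± sd over
replicates of the final-year seed bank (sd, not SEM — the spread reflects
year-to-year stochasticity, and the separate fixed-point oracle covers the
case where 10 years has not fully equilibrated). The package's own
verification uses 200-year deterministic runs for oracle equivalence,
10⁵ draws for distribution-moment recovery, and paired 1000-replicate runs
for Monte Carlo self-consistency; these sizes keep the whole suite within a
few seconds while leaving Monte Carlo error well below the tolerances
tested.

## Known limitations

- No pollen or gene flow between biotypes, no evolution of resistance-allele
  frequency; the two populations are simulated in isolation.
- No economics (control costs, yield loss).
- Per-cohort density dependence only (no between-cohort competition).
- The beta/normal sampling frequency (yearly), the method-of-moments
  inversion, and the zero-truncation of fecundity are modelling choices the
  published tables do not constrain.
- The synthetic climatology is a stand-in; quantitative equilibria depend
  on it and should not be read as site predictions.
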