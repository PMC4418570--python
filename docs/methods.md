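# Methods

`daniopond` couples an organism-level dynamic energy budget (DEB) model of
zebrafish (*Danio rerio*) to a spatial individual-based model (IBM) of a
36 m² tropical pond with an explicit food web and monsoon-climate forcing,
plus the sensitivity-analysis and calibration machinery needed to study
the coupled system.  This note records the model equations, the design
choices made where the design was genuinely open, the numerical settings,
and the limits of what the test suite demonstrates.

## 1. Organism model (DEB)

State per fish: scaled reserve density `e` (–), scaled length
`l = L / L_inf` (–), and egg buffer `R` (cumulative unspawned eggs).  The
dynamics are a food-limited DEB variant with fixed sizes at first feeding
(`l_b`) and puberty (`l_p`); maturity is not tracked as a state variable.

```
s_f(l)  = α · [1 − (1 + l_f³/l³)⁻¹]                    ingestion reduction
de/dt   = c(T) · k_M g / l · [(1 − s_f) f − e]          (f = 0 below l_b)
dl/dt   = r_B (e − l),   r_B = c(T) · k_M g / (3(e+g))
dR/dt   = c(T) · R_M/(1−l_p³) · [(g+l)/(g+e) · e l² − l_p³]⁺   (0 below l_p)
```

`f ∈ [0,1]` is the scaled functional response.  `s_f` makes small fish
assimilate only a fraction `1 − s_f` of encountered food, which turns the
otherwise von Bertalanffy physical-length curve sigmoid; with `s_f ≡ 0`
and `e = f = 1` the model reduces exactly to von Bertalanffy growth (a
closed-form test oracle).  Post-puberty males carry an appetite factor:
`f_male = f_lim · f`.

Compound parameters follow the standard DEB definitions:
`E_m = p_Am / v̇`, `g = E_G / (κ E_m)`, `k_M = ṗ_M / E_G`,
`L_m = κ p_Am / ṗ_M`, `L_inf = L_m / δ`.  With the reference values this
gives `g ≈ 0.427`, `k_M ≈ 0.187 d⁻¹` and `L_inf ≈ 37.5 mm`, consistent
with the 35–43 mm asymptotic size of well-fed females.

**Temperature.**  All rate parameters (`p_Am`, `v̇`, `ṗ_M`) share one
Arrhenius factor `c(T) = exp(T_A/T_R − T_A/T_K)`; ratios (`g`, `E_m`) are
temperature-invariant.  The reproduction rate is a rate like any other and
is multiplied by the same factor — the model fits fecundity at both 26 and
29 °C only if `dR/dt` is temperature-dependent.  A useful invariant
follows: simulating warm and rescaling time by `c(T)` reproduces the
reference-temperature trajectory (tested).

**Allometry.**  `W = exp(W_a ln L + W_b)` with `W` in mg and `L` in mm
(natural logarithms).  Only this convention puts a 30 mm fish near 0.3 g;
a log₁₀ reading of the same constants gives absurd masses.

**Integration.**  Forward Euler with 10 substeps per day (the DEB
sub-step of the daily population schedule).  `l` is floored at 10⁻⁴;
shrinking (`e < l`) is allowed and starvation never kills (adult
zebrafish survive three weeks of fasting).  Eggs are not modelled
energetically: hatchlings enter at `l_b` with `e = 1`, incubation handled
by a degree-day clock (below).  An adaptive RK45 integration of the same
equations serves as a test-only oracle; the Euler error at dt = 0.1 d is
< 0.1 mm in physical length over 400 days and converges at order 1.

## 2. Pond population model (IBM)

A 30 × 30 grid of 20 × 20 cm patches, 0.5 m deep (18 m³): 207 vegetation
patches (juvenile refuge), 207 breeding-ground patches (one male
territory each), the rest open water.  Edges do not wrap.  Founding
population: 300 juveniles + 35 males + 35 females; juvenile scaled
lengths are drawn uniformly between `l_b` and `l_p`, adults between `l_p`
and 0.92, ages uniformly in 20–150 d (juveniles) and 200–500 d (adults),
reserve densities in 0.8–1.0, female egg buffers in 0–R_τ.  These founder
distributions are unconstrained by data and are deliberately broad; after
the customary three-year stabilisation they have no visible influence.

Daily schedule (fixed order): (1) environment, food-web step and the
shared functional response; (2) movement in uniformly random order;
(3) survival; (4) DEB growth of survivors; (5) hatching, puberty,
spawning; (6) summaries.  A census identity (today's count = yesterday's
+ hatched − died) is asserted every single day.

**Movement.**  Juveniles step to a random vegetated Moore neighbour when
not already on vegetation (random neighbour otherwise); territory-less
males claim a free breeding patch in their neighbourhood — first in
random order wins — or move randomly; spawning-ready females jump to a
neighbouring patch with a free territorial male; everyone else moves
randomly within the Moore neighbourhood.  Juvenile moves are
order-independent (no interaction, no patch capacity) and are executed
vectorised; the serial random order is kept exactly for the interacting
adult behaviours.  This scheduling is behaviourally equivalent to a full
serial shuffle and is the main throughput optimisation.

**Survival.**  Daily death probability
`m = π_a π_c W^π_b + π_d D·[juvenile] + π_e (age − π_g)⁺`, clamped to
[0, 1]: a Lorenzen-type allometric term (small fish die faster), a
density term (D = total fish biomass, g m⁻³) applied to juveniles only,
and linear senescence past `π_g`.  Vegetation confers no survival bonus
(all juveniles reach vegetation anyway, there being no patch capacity).

**Eggs and sex.**  A spawning female on the patch of a free territorial
male (one female per male per day, reproduction window open, buffer
≥ R_τ) produces one brood of exactly R_τ = 263 eggs, the observed mean
clutch; the buffer keeps the remainder.  Broods lose eggs to predation
(binomial thinning at π_p per day) and accumulate degree-days
`(T − H_b)⁺`; at `H_a` degree-days the brood hatches with success
`H_max · H_½ / (H_½ + female density)`.  Each brood draws a genetic
sex-ratio component `G ~ N(SR_μ, SR_σ)` truncated to [0, 100] at
spawning; the male fraction `clamp₀¹(G/100 + SR_a (T̄ − SR_b))` uses the
mean incubation temperature, so warm incubation feminises broods
(`SR_a < 0`).  Latent sex is fixed at hatching and revealed at puberty
(`l ≥ l_p`).

**Inter-individual variability.**  Each fish carries a lognormal
multiplier (median 1, log-sd σ = 0.235) on its functional response,
clamped so `f_ind ∈ [0, 1]`.

**Reproduction window.**  Spawning requires photoperiod ≥ 12 h AND water
≥ 22.5 °C.  The photoperiod gate dominates the seasonality of juvenile
recruitment.

## 3. Food web

Six pools: autotrophic `A` and heterotrophic `H` food (kcal pond⁻¹),
dissolved inorganic N and P (mg L⁻¹), sediment N and P (g).  The original
pond-aquaculture ODE system is not reproducible from the published
constants alone, so the module is a structural reconstruction in which
every flux is named after exactly one rate constant (making coverage
auditable):

* phytoplankton growth `λ_max · min(light, nutrient) · θ(T) · A`, with
  light = (photoperiod/12 h, capped at 1) · exp(−Ir_a A − Ir_b H)
  (self-shading) and nutrient = the Liebig minimum of two Monod terms
  (`h_n`, `h_p`);
* autotroph respiration `K_r A` and transfer `K_ml A` into `H`;
  heterotroph sedimentation `K_s H` and decomposition `K_d H`;
* nitrogen: phytoplankton demand `K_an·growth` met first by atmospheric
  fixation `K_n A` and then by dissolved uptake; sediment release
  `K_sn N_s`; mineralisation return `K_hn K_d H`; organic settling
  `K_hn K_s H`; loss to air `K_nl N_w V`; fish excretion
  `K_fn · consumption`;
* phosphorus analogous, with the two velocities (m d⁻¹) converted to
  first-order rates by the water depth: release `(K_pr/W_d) P_s`,
  dissolved-P settling `(K_ps/W_d) P_w V`.

Design choices in this reconstruction:

* **Temperature acts on all biological rates.**  The Gaussian temperature
  factor θ(T) multiplies growth *and* respiration, transfer,
  sedimentation, decomposition and sediment mineralisation.  These are
  all metabolic/microbial processes; leaving the losses
  temperature-independent makes winter production fall below fixed losses
  and the food web collapses every cool season, which contradicts the
  observed annual cycling of such ponds.
* **Fixation is capped by the concurrent loss to air**, so the atmosphere
  is never a net N source.  Without the cap, the prescribed flux list
  violates the closed-system requirement that total N (water + sediment +
  plankton-bound) never increase when monsoon inputs are off; with it,
  the non-increase is structural and is property-tested daily over a
  simulated year.
* **Daily-step guards.**  New production cannot take up more dissolved N
  or P than the pools hold (a 1-day Euler step would otherwise overshoot
  fast-draining pools); combined outfluxes of a dissolved pool are scaled
  down to the stock; pools are floored at zero and flooring beyond
  rounding is logged as a mass-balance warning.
* **Monsoon inputs.**  During the monsoon window (days-of-year 152–273 by
  default) each day adds `F_inputs` of the reference stocks
  (`N_ref = 2000 g`, `P_ref = 200 g`) to the dissolved pools, standing in
  for runoff; this is what makes the monsoon the high-food season and
  approximately compensates the slow annual N and P losses.
* **Initial pools** (A = H = 500 kcal, N_w = 0.2 and P_w = 0.02 mg L⁻¹,
  N_s = 800 g, P_s = 80 g) are scaled from typical vegetated-pond
  standing crops and sediment nutrient densities (tens of g N m⁻²); none
  of these appear in the published tables.

**Functional response.**  All fish share one daily
`f = F / (F + s·B)` with `F = A + H` (kcal) and `B` the fish biomass in
kcal (`G2Kcal` kcal g⁻¹) — paralleling feeding, applied before individual
scatter and the male factor.  Realized consumption, removed from `A` and
`H` in proportion to pool size, is `f` times the temperature-corrected
maximum assimilation flux `Σ p_Am (1 − s_f) (δ l L_inf)²` converted at
4184 J kcal⁻¹ (no ingestion/assimilation overhead is published, so
assimilation is used as the demand).  A structural consequence of this
saturating form with s ≈ 21: a population can only sustain `f ≈ 0.5–0.6`
if the plankton pools hold roughly an order of magnitude more energy than
the fish do.  The pond therefore equilibrates with `A + H` of a few
thousand kcal against a fish standing stock of a few hundred — the
opposite ordering to the published description of the food panels, which
cannot be reconciled with this `f` form.

## 4. Climate forcing

Scenarios are day-indexed (temperature °C, photoperiod h) series, read
from a documented three-column TSV (`day T photoperiod`, `#` comments,
optional header) or generated.  The generator emulates the Kolkata
monsoon climatology: sinusoidal water temperature (default 19–31 °C,
warmest in early June) and astronomical day length at 22.57° N from the
standard solar-declination formula.  Simulation day 1 defaults to 1 May.
Annual series extend cyclically; queries interpolate linearly between
records.

## 5. Calibration

**DEB (Bayesian MCMC).**  `DEBCalibration` fits, by default, the full
free set {δ, p_Am, v̇, κ, α, l_b, l_f, ṗ_M, E_G, E_0, R_M, f_lim} plus
one latent `f` per experimental group (l_p and L_0 stay fixed).  The
likelihood is Gaussian on observed mean lengths (sd from the data,
floored at 0.1 mm) and on cumulative egg counts (common σ = 25 eggs).
Sampling is on unconstrained scales (log / logit) with moderately
informative priors centred on the reference values (log-sd 0.15, logit-sd
0.4; group `f` flat on (0, 1)).  The prior widths matter: the growth data
identify mainly the product `f κ p_Am/(ṗ_M δ)`, so the posterior is a
long curved ridge, and priors much wider than ±15 % leave the ridge so
extended that independent chains cannot traverse it in any reasonable
run — the original calibration likewise used informative priors.

The sampler is a two-stage adaptive random-walk Metropolis: a
component-wise warmup (Robbins–Monro step adaptation, target acceptance
0.44) followed by joint proposals from the empirical covariance of the
chain (scale 2.38/√d, re-estimated every 200 iterations, 5 % small
isotropic moves), run as three independent chains with over-dispersed
admissible starts; the first half of each chain is burn-in.  Convergence
is judged by the classic Gelman–Rubin potential scale reduction
(cross-checked against `arviz.rhat` in the tests) with the conventional
1.2 threshold; when a fit misses the threshold the chains are re-run at
doubled length (up to 4×), the standard response to a failed convergence
diagnostic.  Typical problem sizes: 3 × 40 000 iterations converge in
~2 minutes; synthetic-data refits of the three-parameter subset
{p_Am, ṗ_M, κ} recover the generating values inside the central 95 %
credible intervals in ≥ 90 % of repeated syntheses (tested with 20).

**IBM (genetic algorithm).**  The three population-level parameters
(π_a, π_d, F_inputs — the set marked "fitted" in the reference table;
the accompanying text names π_c instead of π_d, an inconsistency resolved
in favour of the table) are searched by a generational GA with tournament
selection (size 3), blend crossover (rate 0.7), Gaussian mutation (rate
0.01, sd 10 % of range), population 50 and one elite.  The objective is
the sum of squared differences between normalised 1-mm length histograms
of fish above the 18.4 mm sampling cutoff at day 1110; all-extinct
candidates score +∞.  The evaluator is injectable, so the search logic is
tested against a cheap surrogate with a known optimum, and the best-so-far
distance is monotone by elitism.

## 6. Sensitivity analysis

**Sobol (DEB layer).**  Scrambled-Sobol' Saltelli sampling (blocks A, B,
AB_i), first-order indices by the Saltelli-2010 estimator and total
indices by Jansen's.  Default factors: experimental temperature (22–32 °C),
reference temperature (±2 %), δ, p_Am, ṗ_M (±20 %), κ (±20 %, capped
below 1), f (0.5–1), plus the mandatory dummy.  Outputs: predicted length
at 25, 50, 75, 100, 200, 400 dpf and cumulative eggs at 100, 200,
400 dpf.  The published ranges are not recoverable, so rankings — not
index values — are the comparison surface: the temperature, assimilation,
feeding, maintenance, allocation and shape parameters dominate, and the
dummy sits at the noise floor.

**Morris (full IBM).**  Classic r-trajectory one-at-a-time design on an
even-level grid (Δ = p/(2(p−1))), elementary effects normalised by the
unit-scale step; μ, μ* and σ per parameter and the composite global index
`√(μ*² + σ²)` used for ranking (the source plots a "global index" without
a formula; this Euclidean composite is the documented choice).  Outputs
are replicate-averaged abundance, juvenile frequency and stage mean
lengths at the post-stabilisation days 1095–1400; replicate count and
horizon are configurable and desk-scale by default (the full protocol of
30 replicates per point is expensive and reserved for dedicated runs).
The estimators are validated on analytic models: exact coefficients on a
linear model, zero μ*/σ for the dummy, positive σ under interaction, and
the Ishigami benchmark against its closed-form indices.

## 7. Synthetic data

The fixture generators stand in for the unavailable experimental and
field datasets, always by running the model itself forward:

* growth: three feeding groups at 27 °C measured at 49–107 dpf (eight
  days), Gaussian noise (default sd 0.5 mm) on per-fish lengths, means ±
  sd reported;
* fecundity: cumulative eggs monitored daily for 21 d at 29 °C and 11 d
  at 26 °C from adult females, noise accumulated monotonically;
* field histogram: a full IBM run sampled for 120 fish above a length
  cutoff, binned at 1 mm.

They emulate the *layout* of real campaigns, not their biology: noise is
iid Gaussian, there are no tank effects, no measurement censoring other
than the explicit length cutoff, and the generating model is by
construction the fitted model.  Passing calibration tests therefore
demonstrates internal consistency (the machinery recovers what generated
the data), not that the model fits real zebrafish data.

## 8. Problem sizes and reproducibility

Defaults: 1110-day runs (per the reference configuration); the seasonal
acceptance analysis uses 30 replicates × 4 years with statistics from the
final year (the test suite uses 8 replicates of the same protocol), which
keeps a full desk run within minutes on one core.  All stochastic paths
flow from a single integer seed: replicate r of a run derives its
generator as `seed + r` (CLI) or a documented affine map (acceptance
script), chains as `1000·seed + 17·chain + 1`, and every test either
fixes its seed or runs hypothesis in derandomised mode.  Identical seed
and configuration give bitwise-identical daily summaries.

## 9. Known limitations

* The food-web ODEs, the survival formula, the original climate trace and
  the compound-parameter supplement are reconstructions; they honour the
  published constants and qualitative claims but are not the authors'
  originals.
* The simulated annual cycle reproduces the breeding-season flood of
  small fish (the censored fraction reaches ~99 % vs the published 91 %)
  but over-clears it afterwards: outside the breeding season the stalled
  juvenile cohort either grows past 15 mm or dies, so the within-year
  minimum of the ≤ 15 mm fraction falls to ~0 % instead of the published
  17 %.  A shallower winter minimum would require the dry-season food
  level to stall juvenile growth just below the sampling cutoff — highly
  sensitive to the unavailable winter food/climate details.
* Single pond, no immigration, no cannibalism or dominance, no
  water-level dynamics; energy for reproduction outside the breeding
  window is dissipated rather than stored.
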