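# daniopond

Mechanistic simulation of a wild-type zebrafish (*Danio rerio*)
population in an isolated tropical pond, for ecological risk assessment
and population ecology: an organism-level **dynamic energy budget (DEB)**
model drives growth and reproduction of every fish, a spatial
**individual-based model (IBM)** adds behaviour, survival and
recruitment on a 30 × 30 patch pond grid, and a **pond food-web
sub-model** closes the feedback between fish biomass and food
availability under Kolkata-style monsoon climate forcing (temperature +
photoperiod).  The package also ships the machinery to analyse and fit
the model: Sobol and Morris global sensitivity analysis, Bayesian MCMC
calibration of the DEB parameters with Gelman–Rubin diagnostics, and a
genetic-algorithm search for the population-level survival/food-input
parameters.

It is written for ecotoxicologists and population modellers who need to
extrapolate from laboratory growth/fecundity measurements to
population-level endpoints.

## The model in brief

Per fish, with scaled reserve density *e*, scaled length *l* = *L*/*L*∞
and egg buffer *R*:

    s_f(l) = α [1 − (1 + l_f³/l³)⁻¹]
    de/dt  = c(T) · k_M g / l · [(1 − s_f) f − e]        (f = 0 below l_b)
    dl/dt  = r_B (e − l),   r_B = c(T) · k_M g / (3(e + g))
    dR/dt  = c(T) · R_M/(1 − l_p³) · [(g+l)/(g+e) · e l² − l_p³]⁺   (0 below l_p)

with Arrhenius temperature correction c(T) = exp(T_A/T_R − T_A/T_K) and
compound parameters g = E_G/(κ E_m), k_M = ṗ_M/E_G, E_m = ṗ_Am/v̇,
L∞ = κ ṗ_Am/(ṗ_M δ).  The size-dependent ingestion reduction s_f makes
juvenile growth sigmoid in physical length.  All fish share one daily
functional response f = F/(F + s·B) from the pond food pools F and the
population biomass B (paralleling feeding); individual lognormal scatter
and a male appetite factor f_lim act on top.  Survival combines
Lorenzen-type allometric mortality, density-dependent juvenile mortality
and senescence; eggs incubate on a degree-day clock, and sex is set by
genetics plus incubation temperature.  See `docs/methods.md` for the
complete account.

## Worked example

Grow a single well-fed female at 27 °C (f = 0.93) and read off length
and cumulative fecundity:

```python
import numpy as np
from daniopond import DEBParams, simulate_trajectory

days = np.array([30., 60., 90., 120., 180., 365.])
L, R = simulate_trajectory(DEBParams(), f=0.93, T=27.0, days=days)
for d, l, r in zip(days, L, R):
    print(f"day {d:5.0f}: length {l:6.2f} mm   cumulative eggs {r:10.1f}")
```

```
day    30: length  17.14 mm   cumulative eggs        0.0
day    60: length  26.21 mm   cumulative eggs     1190.4
day    90: length  30.66 mm   cumulative eggs     6646.5
day   120: length  32.80 mm   cumulative eggs    15020.5
day   180: length  34.31 mm   cumulative eggs    35780.4
day   365: length  34.75 mm   cumulative eggs   106333.0
```

The fish passes puberty (l_p = 0.58, ≈ 21.8 mm) between days 30 and 60,
then approaches its food-limited asymptote ≈ 0.93 · 37.5 mm ≈ 35 mm
while producing on the order of a few hundred eggs per day — the
equation's ceiling is R_M = 406 eggs/d at full size and reserves.

A full pond simulation and the other tools are available from the CLI:

```bash
daniopond simulate      --seed 1 --set run.n_days=1110 --out runs/pond
daniopond simulate-deb  --seed 1 --f 0.93 --temperature 27 --out runs/deb
daniopond sensitivity-sobol --samples 256 --out runs/sobol
daniopond calibrate-deb --chains 3 --iterations 40000 --out runs/mcmc
daniopond calibrate-ibm --generations 10 --out runs/ga
daniopond make-fixtures --out runs/fixtures
```

Each run writes plain-CSV outputs (daily summaries: counts, biomass and
mean length per stage, the shared f, food pools; length histograms above
the 15 and 18.4 mm sampling cutoffs) plus a manifest with the seed and
the resolved configuration, so any run is repeatable byte-for-byte.

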