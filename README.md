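# chumrun

Life-cycle analysis of Japanese hatchery chum salmon (*Oncorhynchus keta*)
marine survival: cohort reconstruction of release-year return rates, regional
clustering, climate/predator/competitor covariate construction, and
log-linear regression with exhaustive AICc model selection.

Japan releases over a billion hatchery chum fry per year, and adult returns
have fallen sharply since the late 1990s. The analysis this package
implements asks which hypothesized stressors — hatchery carryovers (egg size,
fecundity, fry size-at-release), ocean conditions (coastal and high-seas
SST), and predators/competitors (a range-shifting coastal predator, Russian
and North American pink/chum salmon abundance) — covary with the marine
survival of each release-year cohort in each coastal management region.

## The method

**Cohort reconstruction.** An age-*a* fish from the cohort released in year
*t* returns in year *t + a − 1*. Return-year totals *y* are split across
cohorts with survey-weighted age proportions
p̂ₐ = Σₕ pₐₕ nₕ / Σₕ nₕ:

    Ŷ_t = Σ_{a=2..5} y_{t+a−1} · p̂_{a, t+a−1},      R̂_t = Ŷ_t / X_t

where *X_t* is the number of fry released. R̂_t is the marine-survival
index. Recent years without surveys are imputed by a recursive 3-year moving
average. Regional series are compared by the 1 − r correlation distance and
a neighbor-joining tree, which motivates pooling similar regions
(merged rates are ΣŶ/ΣX, never means of rates).

**Regression.** Per region, the response is log R̂_t and the candidate
covariates (lag-aligned to release year, e.g. a *t* + 2 competitor index)
are grouped into three subset models: hatchery carryovers, ocean conditions,
predators/competitors. Within every combination of groups the pooled
covariates are screened by sequentially removing the largest variance
inflation factor until all VIF < 3.0, then every subset of the survivors is
fitted by OLS:

    log R̂_t = log β₀ + Σᵢ βᵢ z_{i,t} + ε_t,   ε_t ~ N(0, σ²)

ranked by AICc, and combinations are compared by their minimum AICc (ties
resolve to the most parsimonious). Coefficients are averaged with Akaike
weights over models within ΔAICc < 2. Effect sizes are reported
multiplicatively: exp(β̂) per practical unit with CI exp(β̂ ± 1.96·SE), and
percent change (exp(β̂) − 1) × 100.

**Synthetic data.** Every stage is testable without downloads: a generator
simulates the same log-linear survival model with known coefficients,
integerizes cohort returns with exact conservation, draws multinomial age
surveys, and produces a seasonal-cycle-plus-trend SST grid and a catch
matrix with one injected "northward-shifting predator".

## Worked example

Run the numbered analysis scripts from the repository root (each writes its
tables under `results/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_reconstruct.py
python analysis/03_cluster.py
python analysis/05_screen_predators.py
python analysis/06_regression.py
```

The reconstruction step prints per-region mean return rates with 5th/95th
percentiles, e.g.

```
  region  mean_pct   p5_pct  p95_pct  n_years
region_1  2.235820 0.795550 5.418570     22.0
region_2  3.508360 0.358054 9.713232     22.0
```

i.e. about 2–4% of released fry return as adults, the realistic order of
magnitude for these programs. The predator screen flags exactly the injected
species (`species_09`, post/pre-breakpoint catch ratio 2.56 with a positive
recent trend), and the regression step recovers the generating model — with
true coefficients `{fry_size: 0.45, sst_at_release: -0.40,
russia_pink_t2: -0.30}` the selected best model per region is exactly that
support, e.g.

```
region_3: best model ['fry_size', 'sst_at_release', 'russia_pink_t2'] (adj R2 0.73)
  coefficients: {'intercept': -3.88, 'fry_size': 0.456, 'sst_at_release': -0.304, 'russia_pink_t2': -0.245}
  predicted-vs-observed r = 0.94 (t = 12.38), QQ fraction inside envelope = 0.95
```

(the intercept sits near log 0.02 = −3.91, the generator's baseline 2%
survival).

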