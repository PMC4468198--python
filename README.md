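# phenorisk

Temperature-driven phenology modelling and pest-risk mapping for maize
stem borers and their larval parasitoids along tropical mountain
gradients — with a projection of the maize yield losses their activity
implies under climate warming.

Lepidopteran stem borers (the crambid *Chilo partellus* in warm
lowlands, the noctuid *Busseola fusca* in cool highlands) are major
maize pests in East Africa; the braconid parasitoids *Cotesia flavipes*
and *C. sesamiae* provide partial biological control. Because insect
development, survival and reproduction are governed by temperature, a
year of daily station temperatures plus a species' thermal phenology
parameters is enough to ask: can the insect establish here, how many
generations can it complete, and how fast would its population grow —
and how do those answers change as the climate warms? `phenorisk` is
aimed at quantitative ecologists and pest-risk modellers who want that
chain of inference as a tested, scriptable library rather than a GUI.

## What it computes

1. **Phenology** (`phenorisk.phenology`). Stage-wise temperature
   responses: Logan development rate
   `r(T) = ψ[e^{ρ(T−T_b)} − e^{ρ(T_max−T_b)−(T_max−T)/δ}]`,
   exponential-quadratic stage mortality `m(T) = min(1, e^{b₀+b₁T+b₂T²})`,
   logit / complementary-log-log development-time variability, Stinner
   or Hilbert–Logan adult longevity, and quadratic lifetime fecundity
   spread over adult age by a gamma profile.
2. **Cohort life tables** (`phenorisk.lifetable`). A stochastic
   individual-based cohort develops by rate summation under a cosine
   diurnal temperature cycle; from the daily `l_x m_x` schedule the
   five classical parameters follow: `R₀ = Σ l_x m_x`,
   `T = Σ x l_x m_x / R₀`, the intrinsic rate `r_m` solving the
   Euler–Lotka equation `Σ e^{−r x} l_x m_x = 1`, `λ = e^{r_m}`, and
   doubling time `ln 2 / r_m`.
3. **Risk indices** (`phenorisk.indices`). ERI — annual mean of the
   product of daily immature-stage survivals; GI — 365 over the mean
   generation time of twelve monthly cohort launches; AI — annual sum
   of daily `r_m` in log₁₀ units (the decimal power of annual
   population increase); host-parasitoid synchrony as the signed ERI
   difference.
4. **Mapping** (`phenorisk.mapping`). Thin-plate-spline interpolation
   (kernel `r² ln r`, affine trend with DEM elevation as a covariate)
   of station indices over an ESRI ASCII elevation grid, raster
   differencing of scenarios, and altitude profiles of the change.
5. **Yield loss** (`phenorisk.yieldloss`). Per agro-climatic altitude
   zone (lowland tropical < 1000 m, dry mid altitude 1000–1300 m,
   moist transitional 1300–1600 m, highland tropics > 1600 m), OLS of
   observed percent maize loss on zone-mean activity index,
   `Y = β₀ + β₁ A`, and projection of future losses from future AI.
6. **Synthetic data** (`phenorisk.synth`). Seeded generators for
   everything above: a 6-station altitudinal transect (700–1800 m) with
   lapse-rate, seasonal-harmonic and noise structure, a one-sided
   mountain DEM, four canonical species profiles (lowland/highland
   host and parasitoid), monthly warming deltas (default +1.45 °C,
   seasonal range 1.0–1.9 °C), and zone losses from a known linear
   relation plus noise.

## Worked example

```python
from phenorisk.pipeline import run_demo

demo = run_demo(seed=1, n_individuals=200)
print("ERI lowland host :", demo.eri["lowland_host"].round(3))
print("ERI highland host:", demo.eri["highland_host"].round(3))
print("GI  lowland host :", demo.gi["lowland_host"].round(2))
print("AI change        :", (demo.ai_future["lowland_host"]
                             - demo.ai_current["lowland_host"]).round(2))
print("loss fit: beta0=%.2f beta1=%.2f r2=%.3f"
      % (demo.fit.beta0, demo.fit.beta1, demo.fit.r2))
```

prints (stations ordered bottom → top of the gradient):

```
ERI lowland host : [0.836 0.813 0.774 0.718 0.627 0.498]
ERI highland host: [0.741 0.788 0.823 0.841 0.849 0.85 ]
GI  lowland host : [4.39 3.79 3.19 2.67 2.14 1.65]
AI change        : [1.86 1.78 1.82 3.64 5.99 5.71]
loss fit: beta0=29.34 beta1=1.65 r2=0.993
```

Read: the warm-adapted host's establishment index falls with altitude
(0.84 → 0.50) while the cool-adapted host's rises (0.74 → 0.85),
reproducing the classic altitudinal partitioning of the two stem
borers; it completes ~4.4 generations per year at the bottom station
and ~1.7 at the top; warming by 1.0–1.9 °C raises its activity index
at every station, most strongly at high altitude; and the yield-loss
regression refits the relation the synthetic losses were generated
from (true β₀ = 30, β₁ = 1.5) within its standard errors.

The same pipeline is scriptable from the shell — `phenorisk synth`,
`simulate`, `indices`, `map`, `change`, `yieldloss` — each a thin
wrapper over the library (see `phenorisk --help`).

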