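# plovermeta

Multistate mark-recapture estimation and stochastic metapopulation
viability analysis for a disturbance-dependent shorebird: three piping
plover (*Charadrius melodus*) subpopulations on the lower Platte and
Missouri rivers — HC (human-created mining/housing habitat), M1F (the
free-flowing Gavins Point Reach, periodically reset by high-flow dam
releases) and M2 (Lewis and Clark Lake). The package is aimed at
quantitative ecologists who want to estimate survival and dispersal from
encounter histories and project metapopulation persistence under a
recurring-disturbance regime, with a synthetic-data generator that
reproduces the study design so everything runs end-to-end with no field
data.

## What it computes

**Estimation.** Apparent survival φ, resight probability p and transition
probability ψ from multistate encounter histories via the
Arnason–Schwarz likelihood: a forward pass over S strata plus an
absorbing dead state, logit links for φ and p, and a multinomial-logit
link for ψ with "stay" as the reference category. Covariates include a
time-varying age class, hatch date and banding age (juveniles), distance
between subpopulations, reproductive success, and high-flow indicator
variables. Models are ranked by

```
QAICc = 2·nll/ĉ + 2k + 2k(k+1)/(ESS − k − 1)
```

with Akaike weights w_i ∝ exp(−Δ_i/2), model-averaged real estimates with
unconditional SEs, Wald tables (β, SE, |β/SE|, 95% CI), and a four-stage
sequential selection procedure in which distance, success and flow terms
substitute for subpopulation and year effects.

**Projection.** An individual-based annual simulator
(breed → mortality → aging → dispersal → ceiling truncation) with a flood
state machine at M1F: 5%/yr flood probability, reproduction zero and
elevated mortality/emigration in a flood year, carrying capacity reset to
its maximum the following year with an immigration surge and a 3-year
window of low juvenile mortality, then Uniform(0.10, 0.60) annual habitat
decay until the next flood. Outputs are extinction probabilities, times to
first extinction, population sizes, recolonization counts, λ_deter
(= s_ad + s_juv·f/2) and λ_stoch.

## Worked example

```python
import plovermeta as pm

# simulate the study design and refit the generating model
spec, beta_true, truth, scen = pm.generating_model()
hist, cov = pm.simulate_histories(truth, scen, seed=1)
fit = pm.fit(spec, hist, cov, scen.distances)
tab = pm.wald(fit)
print(tab[tab.coefficient.str.startswith("psi:")][
    ["coefficient", "estimate", "se", "t"]].to_string(index=False))

# project the canonical metapopulation scenario
cfg = pm.pva_fixture({"replicates": 200})
res = pm.run_pva(cfg, seed=1)
print("M1F extinction %:", round(100 * res.extinction_probability("M1F")[0], 1))
print("metapopulation N(100):", round(res.mean_size(100), 1))
```

prints (seed 1):

```
           coefficient  estimate    se      t
         psi:intercept    -1.966 0.150 13.137
               psi:age     0.969 0.201  4.817
          psi:distance    -0.011 0.001  9.397
     psi:hf_emigration     1.685 0.230  7.341
    psi:hf_immigration    -2.748 1.011  2.719
psi:posthf_immigration     1.042 0.218  4.783
M1F extinction %: 50.0
metapopulation N(100): 207.9
```

The refit recovers the generating dispersal structure — transitions fall
off at −0.011/km of distance, emigration odds out of the flooded reach
rise ×e^1.7 in a flood year while immigration odds into it collapse
×e^−2.7, and post-flood immigration odds rise ×e^1.0 — and the projection
shows the flooded subpopulation carrying about half the extinction risk of
the metapopulation, which itself persists near 200 adults through the
stability of the human-maintained sites.

A command-line surface wraps the same pipeline:

```
plovermeta simulate --seed 1 --out results/
plovermeta report  --seed 1 --out results/
```

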