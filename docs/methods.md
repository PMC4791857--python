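# Methods

`plovermeta` couples two engines for studying a disturbance-dependent
shorebird metapopulation — three piping plover (*Charadrius melodus*)
subpopulations on the lower Platte and Missouri rivers (HC, a human-created
sand-and-gravel-mine complex; M1F, the free-flowing Gavins Point Reach that
experiences high-flow events; M2, the Lewis and Clark Lake reservoir) —
plus a synthetic-data generator that reproduces the study design so the
whole analysis is runnable and testable without field data.

## 1. Multistate mark-recapture model

### Likelihood

Encounter histories record, for each banded bird and each annual occasion
(2008–2013), the subpopulation where it was resighted or `0` for unseen.
The model is the classical multistate (Arnason–Schwarz) formulation with
three parameter classes:

* apparent survival `φ(origin, interval, age, covariates)`,
* resight probability `p(stratum, occasion, age)`,
* transition probability `ψ(origin → destination, interval, age, covariates)`.

The probability of a history, conditional on first release, is computed by
a forward pass over a hidden state space of S strata plus an absorbing dead
state. At an occasion with a sighting the state collapses to the observed
stratum (factor `p`); at an unseen occasion the live mass is propagated
with factor `1 − p` and the dead mass is carried unchanged (the standard
χ-recursion for unobserved tails). The negative log-likelihood is
`−Σ freq · log P(history)` over unique histories.

Links: logit for `φ` and `p`; multinomial logit for `ψ` with *remain in the
current stratum* as the reference category, so each origin's transition row
(stay included) sums to one under arbitrary covariate values. An exact
gradient is produced by reverse accumulation through the forward pass; it
is cross-checked against central finite differences in the test suite, and
the likelihood itself against a brute-force enumeration of all hidden state
sequences.

### Age, covariates and structural zeros

Age is a time-varying state with no explicit transition matrix: a bird
released as a juvenile (0–1 yr) carries juvenile rates for its first
interval only and adult rates afterwards; the same convention indexes the
juvenile resight class (the first anniversary of a chick release).
Individual covariates (hatch date as season-relative days and age at
banding in days) enter juvenile survival only; adults carry the reference
value 0. Group covariates are the year × subpopulation reproductive output
(chicks fledged/pair, lagged to the interval it opens) and three flow
indicator variables: *high-flow emigration* (out of M1F, interval
2010→2011), *high-flow immigration* (into M1F, same interval) and
*post-high-flow immigration* (into M1F, interval 2011→2012). Survival can
carry the analogous *high flow* and *post high flow* indicators for the
M1F stratum. Juvenile survival at M1F and juvenile emigration out of M1F
are fixed to 0 for the intervals opening in 2010 and 2011 (no chicks
fledged there in the flood years); fixes are applied on the probability
scale after the link, carry no coefficients, and receive no gradient.

### Model selection and inference

Models are ranked by QAICc, `2·nll/ĉ + 2k + 2k(k+1)/(ESS − k − 1)`, with
Akaike weights `w_i ∝ exp(−Δ_i/2)`. Conventions, fixed and documented here
because standard software leaves them implicit:

* **ĉ** is an input (default 1.0); the median-ĉ bootstrap is out of scope.
* **ESS** is the number of release events: every detection at occasions
  1..T−1 exposes the bird to a further interval and counts once.
* **k** is the number of free β coefficients. Structurally confounded or
  boundary coefficients are not auto-deducted; `ModelSpec.k_adjust` allows
  a manual override.
* **Deviance** is `2·(nll − nll_saturated)` with the saturated term the
  exact multinomial maximum per release cohort (release occasion, stratum,
  age class, covariate values).
* Ranking ties break by smaller k, then label, for deterministic reports.

Fits use BFGS with the analytic gradient from a null start plus random
restarts on failure; convergence is declared at a projected-gradient
tolerance of 1e-5 (or a gradient max-norm below 1e-3 when the optimiser
reports precision loss at the optimum — the NLL is of order 10³, so this
is far below one likelihood unit). Standard errors come from the inverse
observed information (finite differences of the exact gradient) scaled by
ĉ; coefficients whose variance is not positive are reported as
unavailable. Real estimates are model-averaged with QAICc weights and the
unconditional-SE formula `Σ w_i sqrt(var_i + (θ_i − θ̄)²)`.

The four-stage sequential selection mirrors the study's procedure: (1)
resight structures under maximal survival/transition, (2) survival
structures, (3) transition structures, (4) biological-hypothesis
substitutions, in which every `sub` in a retained transition structure
becomes `distance` and every `year` becomes one of {success, flow dummies,
flow + success} (with an age × success interaction whenever age is
retained), crossed with flow/success augmentations of survival. The full
catalogue (8 + 8 + 15 + 32 models, some with ~100 coefficients) is
constructible; the default pipeline fits a reduced representative
candidate set (four transition structures under the top survival/resight
structure) so a complete run stays in the minutes range — a problem-size
choice of this package, recorded here rather than hidden in the catalogue.

## 2. Synthetic study generator

The generator draws each released bird through
survive → move → detect per interval under a frozen truth anchored to the
published scale: adult survival 0.70/0.67/0.73 and juvenile (non-flood)
survival 0.34/0.15/0.26 for HC/M1F/M2 (the M1F juvenile value is the
non-flood component consistent with a flood-cycle average of ~0.09);
resight 0.64/0.92/0.88 (adult) and 0.32/0.74/0.66 (juvenile); hatch-date
slope −0.031 and banding-age slope 0.032 on logit juvenile survival; a
transition model with distance slope −0.011/km and flow effects 1.690
(high-flow emigration), −2.279 (high-flow immigration) and 1.010
(post-high-flow immigration) on the multinomial-logit scale. The transition
intercept (−1.82) and age contrast (0.79) are set so mean pairwise rates
match the published adult (0.05) and juvenile (0.11) means given the
distances 182/241/30 km. Release cohorts default to the published banding
totals (93/245, 470/1117, 212/503 adult/juvenile for HC/M1F/M2) split
evenly across occasions, with no M1F juvenile cohorts in 2010–2011; the
annual breakdown is not published, so the even split is an assumption.
Hatch dates are truncated normal deviations around the stratum mean
(SD 14/15/12 d) and banding ages truncated discrete normals (5±6, 1±2,
2±3 d), matching the published phenology.

What the generator does **not** emulate: within-season multiple surveys
(a single Bernoulli detection per year), state-assignment ambiguity
(one state per occasion, resolved upstream in the real protocol),
between-year heterogeneity beyond the flow terms, and any individual
random effects. Passing recovery tests therefore demonstrate correctness
of the estimator under the model's own assumptions, not robustness to
their violation in field data.

## 3. Metapopulation viability simulator

An individual-based annual simulator (sex, age and subpopulation per bird)
with a high-flow state machine at M1F only: floods arrive as an annual
Bernoulli event (p = 0.05, one event per ~20 years; consecutive floods are
allowed, as in 2010–2011). The year order is
**breed → mortality → aging → dispersal → ceiling truncation**, the cycle
of classic PVA software; it is fixed, not configurable, outside the
expectation-mode used by tests.

* **Breeding** — monogamous pairs `min(males, females)`; brood sizes
  Poisson with mean chicks fledged/pair: HC 1.06, M2 1.56, M1F 1.16
  ordinarily (the mean of its non-zero years), 1.80 the year after a flood
  and 0 in a flood year; sex is Bernoulli(0.5).
* **Mortality** — one rate draw per subpopulation × age class × year,
  Normal around the schedule mean with SD = 20% of the baseline rate
  (environmental variation), truncated to [0,1], then applied as
  independent Bernoulli deaths (demographic stochasticity). M1F schedules
  depend on time since the flood: juvenile mortality is 1.0 in a flood
  year, at its low post-flood value for a 3-year window, then climbs by a
  fixed increment per year to a cap; adult mortality is elevated in the
  flood year only.
* **Aging** — survivors age one year (juveniles recruit to adults; age at
  first breeding is 1); a maximum age of 20 is unconstraining at ~76–80%
  adult survival.
* **Dispersal** — per-capita total emigration (adult 0.05/yr, juvenile
  0.11/yr, the published means) is split across destinations inversely
  proportional to distance. Flow multipliers scale movement odds exactly as
  the estimated flow effects do: ×e^1.690 out of M1F and ×e^−2.279 into
  M1F in a flood year, ×e^1.010 into M1F the following year. Per-origin
  totals are capped below 1.
* **Carrying capacity** — HC (123) and M2 (70) are static, management-
  maintained ceilings. M1F habitat resets to K_max the year after a flood,
  erodes by a Uniform(0.10, 0.60) fraction in every ordinary year
  (vegetation encroachment/erosion), and is inundated (no breeding, no
  ceiling cull) in the flood year itself. Below a quasi-extinction
  threshold (18 adults ≈ 9 pairs) the remaining sliver of sandbar is
  treated as non-supporting and K collapses to 0. The ceiling is enforced
  as a probabilistic cull (each bird dies with probability 1 − K/N when
  N > K) rather than a hard cap.
* **Extinction bookkeeping** — a subpopulation is extinct when it lacks at
  least one male or one female; a recolonization is an extinct
  subpopulation regaining both sexes at the annual census. The run is
  bit-identical under a fixed seed (one spawned generator per replicate).

`λ_deter = s_ad + s_juv·f/2` is the dominant eigenvalue of the female
two-stage projection; `λ_stoch` is `exp(mean log(N_{t+1}/N_t))` over
replicate-years with positive counts, measured into the *pre-truncation*
count of year t+1 so the ceiling cull does not deflate realised growth
(whether the reference software measures pre- or post-truncation is not
documented; this choice is fixed here).

### Calibration of the canonical scenario

The reference model's exact mortality functions and per-pair dispersal
percentages are not published, so the canonical scenario anchors every
structural element listed above and calibrates the remaining free shape
once, then freezes it in `data/canonical_study.json`. Two points deserve
emphasis:

* The PVA uses *true* survival, which must exceed the mark-recapture
  *apparent* survival (apparent survival confounds mortality with
  permanent emigration, and the simulator models dispersal explicitly).
  The frozen baselines are HC 0.80/0.65 (adult/juvenile), M2 0.78/0.48,
  M1F 0.72 adult with the juvenile time-since-flood ramp (0.50 in the
  3-year window, +0.06/yr, cap 0.95). These imply intrinsic λ of ~1.1
  (HC), ~1.1 (M2) and a declining M1F between floods, the published
  pattern of deterministic growth rates.
* M1F's post-flood ceiling K_max = 3800 makes the realised 100-year mean
  carrying capacity ≈ 477 adults under the stationary flood/decay process
  (the mean works out to ≈0.13·K_max), matching the published average
  while the subpopulation itself stays far below it.

Initial conditions (not published): year 1 is the year after a
habitat-creating event at M1F (K at maximum), with 123/200/69 adults in
HC/M1F/M2 split evenly by sex and staggered starting ages.

## 4. Reporting

Report tables round rates and reproductive output to 2 decimals and
coefficients to 3, matching print precision; every mean row is recomputed
from its own column. The pipeline runs all stages from one master seed
split hierarchically per stage (`numpy.random.SeedSequence.spawn`), writes
a provenance record (seed, config hash, versions), and is byte-identical
across reruns with the same inputs.

## Known limitations

* QAICc values are not comparable to the published table without the raw
  data, the software's exact ESS convention and its ĉ estimate; rankings
  and weights are, within this package's stated conventions.
* No genetics (inbreeding, drift), no density-dependent fecundity beyond
  the ceiling, no delayed first-year breeding phenology, no correlated
  disturbances between subpopulations, no alternative flow-regime
  scenarios.
* Whether year effects in survival are interval- or occasion-indexed in
  the reference software is ambiguous; here they index intervals.
* The simulator's individual-based engine treats a year as a single step;
  within-season renesting is absorbed into the per-pair fledging rate.
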