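"""Individual-based stochastic metapopulation viability simulator.

Simulates three subpopulations of a disturbance-dependent shorebird with a
high-flow state machine at the single flow-affected subpopulation:

* floods arrive as an annual Bernoulli event (default probability 0.05);
* a flood year blocks reproduction and elevates mortality and emigration at
  the flooded subpopulation while suppressing immigration into it;
* the year after a flood resets the flooded subpopulation's carrying
  capacity to its maximum (newly created habitat), draws extra immigrants,
  and opens a multi-year window of low juvenile mortality;
* in ordinary years the flooded subpopulation's carrying capacity erodes by
  a Uniform(0.10, 0.60) fraction annually (vegetation encroachment and
  erosion) and juvenile mortality climbs once the low-mortality window ends.

Within each simulated year the event order is breed -> mortality -> aging ->
dispersal -> ceiling truncation, mirroring the cycle of classic PVA software.
Environmental variation perturbs each year's mortality rates (Normal on the
rate scale, truncated to [0, 1]); demographic stochasticity arises from
Bernoulli survival, Poisson brood sizes and Bernoulli sex at hatch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

HIGH_FLOW = "HIGH_FLOW"
POST_FLOW = "POST_FLOW"
BASELINE = "BASELINE"


@dataclass
class FlowState:
    """Flow-disturbance state: the label is a function of years_since_flow."""

    years_since_flow: int = 2

    def __post_init__(self):
        if self.years_since_flow < 0:
            raise ValueError("years_since_flow must be >= 0")

    @property
    def label(self):
        if self.years_since_flow == 0:
            return HIGH_FLOW
        if self.years_since_flow == 1:
            return POST_FLOW
        return BASELINE


def advance_flow_state(state, flood_probability, rng):
    """One annual step of the flow machine; consecutive floods are allowed."""
    if not 0.0 <= flood_probability <= 1.0:
        raise ValueError("flood probability must lie in [0, 1]")
    if rng.random() < flood_probability:
        return FlowState(0)
    return FlowState(state.years_since_flow + 1)


@dataclass
class MortalitySchedule:
    """Annual mortality for one age class as a function of flow state.

    For juveniles at the dynamic subpopulation the post-flood rate holds for
    ``window_years`` years after a flood and then climbs by
    ``annual_increment`` per year up to ``cap``.
    """

    baseline: float
    flood: float = None
    post_flood: float = None
    window_years: int = 3
    annual_increment: float = 0.0
    cap: float = 1.0

    def __post_init__(self):
        if self.flood is None:
            self.flood = self.baseline
        if self.post_flood is None:
            self.post_flood = self.baseline
        for v in (self.baseline, self.flood, self.post_flood, self.cap):
            if not 0.0 <= v <= 1.0:
                raise ValueError("mortality rates must lie in [0, 1]")

    def rate(self, years_since_flow):
        if years_since_flow == 0:
            return self.flood
        if years_since_flow <= self.window_years:
            return self.post_flood
        r = self.post_flood + self.annual_increment * (years_since_flow
                                                       - self.window_years)
        return min(r, self.cap)


@dataclass
class SubpopConfig:
    """Demography and habitat dynamics of one subpopulation."""

    name: str
    K_static: int = None                 # static ceiling (adults)
    K_max: int = None                    # post-flood ceiling for the dynamic subpop
    K_decay_range: tuple = (0.10, 0.60)  # annual habitat loss fraction
    K_floor: int = 0
    K_quasi_zero: int = 0                # below this the habitat supports no pairs
    flood_probability: float = 0.0
    juvenile_mortality: MortalitySchedule = None
    adult_mortality: MortalitySchedule = None
    ev_sd_fraction: float = 0.20         # EV SD as a fraction of baseline mortality
    fecundity_baseline: float = 0.0      # chicks fledged / pair
    fecundity_flood: float = 0.0
    fecundity_post_flood: float = None

    def __post_init__(self):
        if (self.K_static is None) == (self.K_max is None):
            raise ValueError(f"{self.name}: exactly one of K_static/K_max")
        if not 0.0 <= self.flood_probability <= 1.0:
            raise ValueError("flood probability must lie in [0, 1]")
        lo, hi = self.K_decay_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("decay fractions must lie in (0, 1)")
        if self.fecundity_post_flood is None:
            self.fecundity_post_flood = self.fecundity_baseline
        for f in (self.fecundity_baseline, self.fecundity_flood,
                  self.fecundity_post_flood):
            if f < 0:
                raise ValueError("fecundity must be >= 0")

    @property
    def dynamic(self):
        return self.K_max is not None

    def fecundity(self, years_since_flow):
        if not self.dynamic:
            return self.fecundity_baseline
        if years_since_flow == 0:
            return self.fecundity_flood
        if years_since_flow == 1:
            return self.fecundity_post_flood
        return self.fecundity_baseline


def update_carrying_capacity(K, state, cfg, rng):
    """Annual carrying-capacity update.

    Static subpopulations are unchanged.  The dynamic subpopulation resets to
    K_max the year after a flood, loses a Uniform fraction of habitat in
    ordinary years (with K below K_quasi_zero collapsing to the floor), and
    is inundated (K = 0) in the flood year itself.
    """
    if not cfg.dynamic:
        return K
    if state.label == HIGH_FLOW:
        return 0
    if state.label == POST_FLOW:
        return cfg.K_max
    d = rng.uniform(*cfg.K_decay_range)
    K = int(K * (1.0 - d))
    if K < cfg.K_quasi_zero:
        K = cfg.K_floor
    return max(K, cfg.K_floor)


@dataclass
class DispersalConfig:
    """Annual dispersal probabilities per ordered subpopulation pair.

    Baseline per-capita total emigration (per age class) is split across
    destinations inversely proportional to distance.  Flow multipliers scale
    movement out of / into the flow-affected subpopulation during flood and
    post-flood years (odds-style multipliers on the baseline rates).
    """

    stratum_names: list
    base: np.ndarray                     # [2 (adult, juvenile), S, S]
    flow_stratum: str = "M1F"
    out_flood_multiplier: float = 1.0
    in_flood_multiplier: float = 1.0
    in_postflood_multiplier: float = 1.0

    def __post_init__(self):
        self.base = np.asarray(self.base, dtype=float)
        S = len(self.stratum_names)
        if self.base.shape != (2, S, S):
            raise ValueError("base dispersal must be [2, S, S]")

    @classmethod
    def from_totals(cls, stratum_names, distances_km, adult_total,
                    juvenile_total, **kw):
        S = len(stratum_names)
        base = np.zeros((2, S, S))
        for a, tot in enumerate((adult_total, juvenile_total)):
            for r in range(S):
                w = np.array([0.0 if s == r else 1.0 / distances_km[r, s]
                              for s in range(S)])
                if w.sum() > 0:
                    base[a, r] = tot * w / w.sum()
        return cls(stratum_names, base, **kw)

    def rates(self, flow_states):
        """[2, S, S] movement probabilities given current flow states."""
        P = self.base.copy()
        if self.flow_stratum not in self.stratum_names:
            return P
        fi = self.stratum_names.index(self.flow_stratum)
        lab = flow_states[fi].label
        if lab == HIGH_FLOW:
            P[:, fi, :] *= self.out_flood_multiplier
            P[:, :, fi] *= self.in_flood_multiplier
        elif lab == POST_FLOW:
            P[:, :, fi] *= self.in_postflood_multiplier
        np.einsum("aii->ai", P)[:] = 0.0
        tot = P.sum(axis=2, keepdims=True)
        over = tot > 0.98
        if np.any(over):     # keep per-origin totals below 1
            P = np.where(over, P * 0.98 / np.where(tot > 0, tot, 1.0), P)
        return P


@dataclass
class PVAConfig:
    subpops: list
    dispersal: DispersalConfig
    replicates: int = 1000
    horizon: int = 100
    initial: dict = field(default_factory=dict)    # name -> (males, females)
    max_age: int = 20
    initial_years_since_flow: int = 1

    def __post_init__(self):
        if self.replicates < 1 or self.horizon < 1:
            raise ValueError("replicates and horizon must be >= 1")
        names = [s.name for s in self.subpops]
        if names != list(self.dispersal.stratum_names):
            raise ValueError("dispersal strata must match subpop order")
        for name, (m, f) in self.initial.items():
            if name not in names or m < 0 or f < 0:
                raise ValueError(f"bad initial size entry {name!r}")

    @property
    def names(self):
        return [s.name for s in self.subpops]


# ---------------------------------------------------------------------------
# JSON scenario config
# ---------------------------------------------------------------------------

def config_from_dict(doc):
    subpops = []
    for sd in doc["subpops"]:
        subpops.append(SubpopConfig(
            name=sd["name"],
            K_static=sd.get("K_static"),
            K_max=sd.get("K_max"),
            K_decay_range=tuple(sd.get("K_decay_range", (0.10, 0.60))),
            K_floor=sd.get("K_floor", 0),
            K_quasi_zero=sd.get("K_quasi_zero", 0),
            flood_probability=sd.get("flood_probability", 0.0),
            juvenile_mortality=MortalitySchedule(**sd["juvenile_mortality"]),
            adult_mortality=MortalitySchedule(**sd["adult_mortality"]),
            ev_sd_fraction=sd.get("ev_sd_fraction", 0.20),
            fecundity_baseline=sd["fecundity_baseline"],
            fecundity_flood=sd.get("fecundity_flood", 0.0),
            fecundity_post_flood=sd.get("fecundity_post_flood")))
    dd = doc["dispersal"]
    names = [s.name for s in subpops]
    if "base" in dd:
        disp = DispersalConfig(names, np.asarray(dd["base"]),
                               flow_stratum=dd.get("flow_stratum", "M1F"),
                               out_flood_multiplier=dd.get("out_flood_multiplier", 1.0),
                               in_flood_multiplier=dd.get("in_flood_multiplier", 1.0),
                               in_postflood_multiplier=dd.get("in_postflood_multiplier", 1.0))
    else:
        S = len(names)
        D = np.zeros((S, S))
        for item in dd["distances_km"]:
            i, j = names.index(item["from"]), names.index(item["to"])
            D[i, j] = D[j, i] = float(item["km"])
        disp = DispersalConfig.from_totals(
            names, D, dd["adult_total"], dd["juvenile_total"],
            flow_stratum=dd.get("flow_stratum", "M1F"),
            out_flood_multiplier=dd.get("out_flood_multiplier", 1.0),
            in_flood_multiplier=dd.get("in_flood_multiplier", 1.0),
            in_postflood_multiplier=dd.get("in_postflood_multiplier", 1.0))
    return PVAConfig(
        subpops=subpops, dispersal=disp,
        replicates=doc.get("replicates", 1000),
        horizon=doc.get("horizon", 100),
        initial={k: tuple(v) for k, v in doc["initial"].items()},
        max_age=doc.get("max_age", 20),
        initial_years_since_flow=doc.get("initial_years_since_flow", 1))


def load_config(path):
    with open(path) as fh:
        return config_from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Annual cycle and replicate engine
# ---------------------------------------------------------------------------

@dataclass
class PopulationState:
    """Individuals as parallel arrays: age (years), sex (1 = male), subpop."""

    age: np.ndarray
    sex: np.ndarray
    pop: np.ndarray

    @classmethod
    def initial(cls, cfg, rng):
        ages, sexes, pops = [], [], []
        for i, name in enumerate(cfg.names):
            m, f = cfg.initial.get(name, (0, 0))
            n = m + f
            ages.append(1 + np.arange(n) % 5)   # staggered starting ages
            sexes.append(np.concatenate([np.ones(m, np.int8),
                                         np.zeros(f, np.int8)]))
            pops.append(np.full(n, i, np.int8))
        return cls(np.concatenate(ages).astype(np.int16),
                   np.concatenate(sexes).astype(np.int8),
                   np.concatenate(pops).astype(np.int8))

    def counts(self, S):
        return np.bincount(self.pop, minlength=S)

    def has_both_sexes(self, S):
        male = np.bincount(self.pop[self.sex == 1], minlength=S)
        female = np.bincount(self.pop[self.sex == 0], minlength=S)
        return (male > 0) & (female > 0)


def annual_cycle(state, cfg, flow_states, Ks, rng):
    """One year: breed -> mortality -> aging -> dispersal -> truncation.

    Returns (new_state, pre_truncation_counts).  ``flow_states`` and ``Ks``
    are per-subpopulation (already advanced/updated for this year).
    """
    S = len(cfg.subpops)
    if len(flow_states) != S or len(Ks) != S:
        raise ValueError("flow-state vector length mismatch")
    age, sex, pop = state.age, state.sex, state.pop

    # 1. breeding: monogamous pairs, Poisson brood per pair, Bernoulli sex
    males = np.bincount(pop[(sex == 1) & (age >= 1)], minlength=S)
    females = np.bincount(pop[(sex == 0) & (age >= 1)], minlength=S)
    pairs = np.minimum(males, females)
    new_age, new_sex, new_pop = [age], [sex], [pop]
    for i, sp in enumerate(cfg.subpops):
        f = sp.fecundity(flow_states[i].years_since_flow)
        chicks = rng.poisson(f * pairs[i]) if f > 0 and pairs[i] > 0 else 0
        if chicks:
            new_age.append(np.zeros(chicks, np.int16))
            new_sex.append((rng.random(chicks) < 0.5).astype(np.int8))
            new_pop.append(np.full(chicks, i, np.int8))
    age = np.concatenate(new_age)
    sex = np.concatenate(new_sex)
    pop = np.concatenate(new_pop)

    # 2. mortality: one EV draw per subpop-year-ageclass, Bernoulli deaths
    rates = np.zeros((S, 2))
    for i, sp in enumerate(cfg.subpops):
        y = flow_states[i].years_since_flow
        for a, sched in enumerate((sp.adult_mortality, sp.juvenile_mortality)):
            mu = sched.rate(y)
            sd = sp.ev_sd_fraction * sched.baseline
            r = rng.normal(mu, sd) if sd > 0 else mu
            rates[i, a] = min(max(r, 0.0), 1.0)
    is_juv = (age == 0).astype(np.int8)
    die = rng.random(age.size) < rates[pop, is_juv]
    keep = ~die
    age, sex, pop = age[keep], sex[keep], pop[keep]

    # 3. aging: survivors age one year; cap at max_age
    age = age + 1
    keep = age <= cfg.max_age
    age, sex, pop = age[keep], sex[keep], pop[keep]

    # 4. dispersal: age-1 birds use juvenile (natal) rates
    P = cfg.dispersal.rates(flow_states)
    a_idx = (age == 1).astype(np.int8)
    probs = P[a_idx, pop]                      # [n, S] destination probabilities
    u = rng.random(age.size)
    cum = np.cumsum(probs, axis=1)
    dest = np.argmax(u[:, None] < cum, axis=1)
    moved = u < cum[:, -1]
    pop = np.where(moved, dest, pop).astype(np.int8)

    pre_counts = np.bincount(pop, minlength=S)

    # 5. ceiling truncation (skipped at the flooded subpop in a flood year:
    #    habitat is inundated but flood mortality already applied)
    death = np.zeros(age.size, dtype=bool)
    for i, sp in enumerate(cfg.subpops):
        if sp.dynamic and flow_states[i].label == HIGH_FLOW:
            continue
        n_i = pre_counts[i]
        if n_i > Ks[i]:
            excess_p = 1.0 - Ks[i] / n_i
            m = pop == i
            death[m] = rng.random(n_i) < excess_p
    keep = ~death
    return PopulationState(age[keep], sex[keep], pop[keep]), pre_counts


@dataclass
class PVAResult:
    """Replicate trajectories and viability summaries."""

    names: list
    N: np.ndarray                  # [rep, year, S] adults after truncation
    N_pre: np.ndarray              # [rep, year, S] adults before truncation
    K_dyn: np.ndarray              # [rep, year] dynamic subpop ceiling
    flow_y: np.ndarray             # [rep, year] years_since_flow at dynamic subpop
    extinct_at_horizon: np.ndarray     # [rep, S] bool
    meta_extinct_at_horizon: np.ndarray  # [rep] bool
    first_extinction_year: np.ndarray  # [rep, S]; 0 = never (years are 1-based)
    recolonizations: np.ndarray    # [rep, S]

    def extinction_probability(self, name=None):
        """P(extinct at horizon) with a binomial Monte-Carlo SE."""
        if name is None:
            x = self.meta_extinct_at_horizon
        else:
            x = self.extinct_at_horizon[:, self.names.index(name)]
        p = float(np.mean(x))
        se = float(np.sqrt(p * (1 - p) / len(x)))
        return p, se

    def mean_time_to_extinction(self, name):
        """Mean year of first extinction, conditional on extinction occurring."""
        y = self.first_extinction_year[:, self.names.index(name)]
        y = y[y > 0]
        if y.size == 0:
            return np.nan, np.nan
        return float(y.mean()), float(y.std(ddof=1) / np.sqrt(y.size))

    def mean_size(self, year, name=None):
        idx = year - 1
        if name is None:
            return float(self.N[:, idx, :].sum(axis=1).mean())
        return float(self.N[:, idx, self.names.index(name)].mean())

    def total_recolonizations(self, name):
        return int(self.recolonizations[:, self.names.index(name)].sum())

    def mean_realized_K(self):
        return float(self.K_dyn.mean())

    def summary(self, lambdas=None):
        out = {"subpops": {}, "metapopulation": {}}
        p, se = self.extinction_probability()
        out["metapopulation"] = {
            "extinction_probability": p, "extinction_probability_se": se,
            "mean_N": {str(y): self.mean_size(y) for y in (20, 50, 100)
                       if y <= self.N.shape[1]},
            "lambda_stoch": stochastic_lambda(self)}
        for nm in self.names:
            p, se = self.extinction_probability(nm)
            t, tse = self.mean_time_to_extinction(nm)
            out["subpops"][nm] = {
                "extinction_probability": p, "extinction_probability_se": se,
                "mean_years_to_extinction": t,
                "mean_years_to_extinction_se": tse,
                "mean_N": {str(y): self.mean_size(y, nm) for y in (20, 50, 100)
                           if y <= self.N.shape[1]},
                "recolonizations": self.total_recolonizations(nm),
                "lambda_stoch": stochastic_lambda(self, nm)}
        out["dynamic_subpop_mean_K"] = self.mean_realized_K()
        if lambdas:
            out["lambda_deter"] = lambdas
        return out

    def trajectories(self):
        import pandas as pd
        rep, yr, S = self.N.shape
        ri, yi, si = np.meshgrid(np.arange(rep), np.arange(1, yr + 1),
                                 np.arange(S), indexing="ij")
        return pd.DataFrame({
            "replicate": ri.ravel(), "year": yi.ravel(),
            "subpop": np.array(self.names)[si.ravel()],
            "N_adult": self.N.ravel()})


def run_pva(cfg, seed=0):
    """Run the full replicate set; bit-identical for identical seeds."""
    S = len(cfg.subpops)
    dyn = [i for i, s in enumerate(cfg.subpops) if s.dynamic]
    R, H = cfg.replicates, cfg.horizon
    N = np.zeros((R, H, S), np.int32)
    Npre = np.zeros((R, H, S), np.int32)
    Kd = np.zeros((R, H), np.int32)
    Fy = np.zeros((R, H), np.int32)
    ext_h = np.zeros((R, S), bool)
    meta_ext = np.zeros(R, bool)
    first_ext = np.zeros((R, S), np.int32)
    recol = np.zeros((R, S), np.int32)

    seeds = np.random.SeedSequence(seed).spawn(R)
    for r in range(R):
        rng = np.random.default_rng(seeds[r])
        state = PopulationState.initial(cfg, rng)
        flow = [FlowState(cfg.initial_years_since_flow if sp.dynamic else 2)
                for sp in cfg.subpops]
        Ks = [sp.K_max if sp.dynamic else sp.K_static for sp in cfg.subpops]
        extinct = ~state.has_both_sexes(S)
        for t in range(H):
            for i, sp in enumerate(cfg.subpops):
                flow[i] = advance_flow_state(flow[i], sp.flood_probability, rng)
                Ks[i] = update_carrying_capacity(Ks[i], flow[i], sp, rng)
            state, pre = annual_cycle(state, cfg, flow, Ks, rng)
            N[r, t] = state.counts(S)
            Npre[r, t] = pre
            if dyn:
                Kd[r, t] = Ks[dyn[0]]
                Fy[r, t] = flow[dyn[0]].years_since_flow
            both = state.has_both_sexes(S)
            for i in range(S):
                if extinct[i] and both[i]:
                    recol[r, i] += 1
                    extinct[i] = False
                elif not extinct[i] and not both[i]:
                    extinct[i] = True
                    if first_ext[r, i] == 0:
                        first_ext[r, i] = t + 1
        ext_h[r] = extinct
        male = np.bincount(state.pop[state.sex == 1], minlength=S).sum()
        female = np.bincount(state.pop[state.sex == 0], minlength=S).sum()
        meta_ext[r] = (male == 0) or (female == 0)
    return PVAResult(cfg.names, N, Npre, Kd, Fy, ext_h, meta_ext,
                     first_ext, recol)


# ---------------------------------------------------------------------------
# Growth rates and the deterministic limit
# ---------------------------------------------------------------------------

def deterministic_lambda(adult_survival, juvenile_survival, fecundity):
    """Dominant eigenvalue of the female two-stage projection:
    lambda = s_ad + s_juv * (f / 2)."""
    for s in (adult_survival, juvenile_survival):
        if not 0.0 <= s <= 1.0:
            raise ValueError("survival must lie in [0, 1]")
    if fecundity < 0:
        raise ValueError("fecundity must be >= 0")
    return adult_survival + juvenile_survival * fecundity / 2.0


def stochastic_lambda(result, name=None):
    """exp(mean log(N_{t+1}/N_t)) over replicate-years with N_t > 0.

    Growth is measured into the pre-truncation count of year t+1 so the
    ceiling cull does not deflate the realised growth rate.
    """
    if name is None:
        num = result.N_pre.sum(axis=2)[:, 1:].astype(float)
        den = result.N.sum(axis=2)[:, :-1].astype(float)
    else:
        i = result.names.index(name)
        num = result.N_pre[:, 1:, i].astype(float)
        den = result.N[:, :-1, i].astype(float)
    ok = (den > 0) & (num > 0)
    if not np.any(ok):
        raise ValueError("no eligible year-pairs for stochastic lambda")
    return float(np.exp(np.mean(np.log(num[ok] / den[ok]))))


def expectation_trajectory(cfg, years):
    """Deterministic (expectation-mode) trajectory: Poisson broods, Bernoulli
    deaths and dispersal are replaced by their expectations on real-valued
    stage vectors.  With flood probability 0 and EV disabled this equals the
    two-stage Leslie projection and is used as the analytic cross-check.

    Flood arrival and habitat decay are stochastic events, so in expectation
    mode the flow clock simply counts up from the baseline state and the
    ceilings stay at their initial values; the demographic rates still
    follow the time-since-flow schedules.

    Returns adults[years+1, S] (index 0 = initial)."""
    S = len(cfg.subpops)
    A = np.array([sum(cfg.initial.get(nm, (0, 0))) for nm in cfg.names],
                 dtype=float)
    flow = [FlowState(2) for _ in range(S)]
    Ks = np.array([sp.K_max if sp.dynamic else sp.K_static
                   for sp in cfg.subpops], dtype=float)
    out = [A.copy()]
    for _ in range(years):
        P = cfg.dispersal.rates(flow)
        J = np.array([(A[i] / 2.0) * sp.fecundity(flow[i].years_since_flow)
                      for i, sp in enumerate(cfg.subpops)])
        mj = np.array([sp.juvenile_mortality.rate(flow[i].years_since_flow)
                       for i, sp in enumerate(cfg.subpops)])
        ma = np.array([sp.adult_mortality.rate(flow[i].years_since_flow)
                       for i, sp in enumerate(cfg.subpops)])
        J, A = J * (1.0 - mj), A * (1.0 - ma)
        # aging: juveniles recruit; expectation-mode dispersal with age-1
        # birds (this year's recruits) using the juvenile (natal) rates
        A = (A * (1.0 - P[0].sum(axis=1)) + A @ P[0]
             + J * (1.0 - P[1].sum(axis=1)) + J @ P[1])
        A = np.minimum(A, Ks)
        out.append(A.copy())
        flow = [FlowState(f.years_since_flow + 1) for f in flow]
    return np.array(out)
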