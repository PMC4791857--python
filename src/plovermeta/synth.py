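"""Synthetic data with the statistical structure of the three-subpopulation
piping plover study design.

Generates encounter histories (2008-2013, strata HC / M1F / M2), the
year x stratum covariate table, and the canonical PVA scenario, so the whole
estimation and viability pipeline runs with no external data.  The frozen
truth anchors every rate to the study's published scale: survival, resight
and dispersal means, the logit-scale covariate effects (distance slope,
high-flow dummies, hatch-date and banding-age slopes), the reproductive
output table, and the structural zeros for flow-year juveniles at M1F.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .encounter import (ADULT, JUVENILE, EncounterHistory, Histories,
                        ModelSpec, OccasionCovariates, distance_matrix,
                        mandatory_fixes)
from .pva import config_from_dict

STRATA = ["HC", "M1F", "M2"]
YEARS = [2008, 2009, 2010, 2011, 2012, 2013]
DISTANCES_KM = {("HC", "M1F"): 182.0, ("HC", "M2"): 241.0,
                ("M1F", "M2"): 30.0}

# chicks fledged / pair by breeding season (2008-2012) and subpopulation
SUCCESS_TABLE = {
    "HC": [1.20, 0.61, 0.74, 1.31, 1.44],
    "M1F": [1.14, 0.53, 0.00, 0.00, 1.80],
    "M2": [1.56, 2.61, 1.87, 0.49, 1.27],
}

# banding phenology: (hatch-date SD days, hatch range around the mean,
#                     banding-age mean, SD, max) per stratum
_PHENOLOGY = {
    "HC": (14.0, (-30.0, 42.0), 5.0, 6.0, 24),
    "M1F": (15.0, (-35.0, 34.0), 1.0, 2.0, 16),
    "M2": (12.0, (-27.0, 31.0), 2.0, 3.0, 24),
}

# total banded/encountered birds (adult, juvenile) per stratum
_BANDING_TOTALS = {"HC": (93, 245), "M1F": (470, 1117), "M2": (212, 503)}


@dataclass
class TruthParameters:
    """Generating parameter values on the scales the analysis estimates."""

    phi_cell: np.ndarray            # [2 (adult, juv), S] non-flood survival
    p_cell: np.ndarray              # [2, S] resight probability
    phi_high_flow: float = -0.276   # logit effects on flow-stratum survival
    phi_post_high_flow: float = 0.785
    hatch_slope: float = -0.031     # per day, logit survival (juveniles)
    band_age_slope: float = 0.032
    psi_intercept: float = -1.82    # multinomial-logit transition model
    psi_age: float = 0.79
    psi_distance: float = -0.011    # per km
    psi_hf_emigration: float = 1.690
    psi_hf_immigration: float = -2.279
    psi_posthf_immigration: float = 1.010

    def __post_init__(self):
        self.phi_cell = np.asarray(self.phi_cell, dtype=float)
        self.p_cell = np.asarray(self.p_cell, dtype=float)
        for a in (self.phi_cell, self.p_cell):
            if np.any((a < 0) | (a > 1)):
                raise ValueError("probabilities must lie in [0, 1]")

    def psi_matrices(self, scenario):
        """[2, n_intervals, S, S] transition matrices (rows sum to 1)."""
        S = len(scenario.strata)
        ni = len(scenario.years) - 1
        D = scenario.distances
        fi = scenario.strata.index(scenario.flow_stratum)
        out = np.zeros((2, ni, S, S))
        for a in range(2):
            for t in range(ni):
                for r in range(S):
                    eta = np.zeros(S)
                    for s in range(S):
                        if s == r:
                            continue
                        e = (self.psi_intercept + self.psi_age * (a == 1)
                             + self.psi_distance * D[r, s])
                        if scenario.hf_flag[t]:
                            if r == fi:
                                e += self.psi_hf_emigration
                            elif s == fi:
                                e += self.psi_hf_immigration
                        if scenario.posthf_flag[t] and s == fi and r != fi:
                            e += self.psi_posthf_immigration
                        eta[s] = e
                    ex = np.exp(eta - eta.max())
                    ex[r] = np.exp(-eta.max())
                    out[a, t, r] = ex / ex.sum()
        # structural zeros: juvenile emigration out of the flow stratum in
        # the flood intervals (no fledged chicks were produced there)
        for t in scenario.flood_fix_intervals:
            out[1, t, fi, :] = 0.0
            out[1, t, fi, fi] = 1.0
        return out


@dataclass
class StudyScenario:
    """The frozen three-subpopulation study design."""

    strata: list = field(default_factory=lambda: list(STRATA))
    years: list = field(default_factory=lambda: list(YEARS))
    distances: np.ndarray = None
    success: np.ndarray = None            # [n_intervals, S]
    hf_flag: np.ndarray = None            # high-flow interval (2010 -> 2011)
    posthf_flag: np.ndarray = None        # post-high-flow interval (2011 -> 2012)
    flow_stratum: str = "M1F"
    flood_fix_intervals: tuple = (2, 3)   # intervals opening 2010 and 2011

    def __post_init__(self):
        ni = len(self.years) - 1
        if self.distances is None:
            self.distances = distance_matrix(self.strata, DISTANCES_KM)
        if self.success is None:
            self.success = np.array([SUCCESS_TABLE[s] for s in self.strata]).T
        if self.hf_flag is None:
            self.hf_flag = (np.arange(ni) == self.years.index(2010)).astype(float)
        if self.posthf_flag is None:
            self.posthf_flag = (np.arange(ni) == self.years.index(2011)).astype(float)

    def covariates(self):
        return OccasionCovariates(self.years, self.strata, self.success,
                                  self.hf_flag, self.posthf_flag,
                                  self.flow_stratum)


def study_scenario():
    """The canonical truth and study design (frozen)."""
    truth = TruthParameters(
        phi_cell=np.array([[0.70, 0.67, 0.73],      # adult: HC, M1F, M2
                           [0.34, 0.15, 0.26]]),    # juvenile (non-flood)
        p_cell=np.array([[0.64, 0.92, 0.88],
                         [0.32, 0.74, 0.66]]))
    return truth, StudyScenario()


def generating_model():
    """ModelSpec + true beta reproducing the canonical truth exactly.

    Cell-mean (treatment) coding: intercept = adult HC; 'age' shifts to the
    juvenile row, 'sub'/'age:sub' to the other strata.
    """
    truth, scenario = study_scenario()
    spec = ModelSpec(
        phi=("intercept", "age", "sub", "age:sub", "hatch", "band_age",
             "high_flow", "post_high_flow"),
        p=("intercept", "age", "sub", "age:sub"),
        psi=("intercept", "age", "distance", "hf_emigration",
             "hf_immigration", "posthf_immigration"),
        fixed=mandatory_fixes(scenario.flow_stratum,
                              scenario.flood_fix_intervals),
        label="generating")

    def cells_to_beta(cell):
        l = logit(cell)
        b0 = l[0, 0]
        b_age = l[1, 0] - b0
        b_sub = [l[0, s] - b0 for s in (1, 2)]
        b_int = [l[1, s] - b0 - b_age - b_sub[s - 1] for s in (1, 2)]
        return [b0, b_age] + b_sub + b_int

    beta = (cells_to_beta(truth.phi_cell)
            + [truth.hatch_slope, truth.band_age_slope,
               truth.phi_high_flow, truth.phi_post_high_flow]
            + cells_to_beta(truth.p_cell)
            + [truth.psi_intercept, truth.psi_age, truth.psi_distance,
               truth.psi_hf_emigration, truth.psi_hf_immigration,
               truth.psi_posthf_immigration])
    return spec, np.array(beta, dtype=float), truth, scenario


def default_cohorts(scenario, scale=1.0):
    """Release cohorts [occasion, stratum, age] from the printed banding
    totals, split evenly across occasions (juveniles skip the flood years at
    the flow-affected stratum, when no chicks fledged there)."""
    T, S = len(scenario.years), len(scenario.strata)
    out = np.zeros((T, S, 2), dtype=int)
    fi = scenario.strata.index(scenario.flow_stratum)
    flood_years = {scenario.years[t] for t in scenario.flood_fix_intervals}
    for s, name in enumerate(scenario.strata):
        n_ad, n_juv = _BANDING_TOTALS[name]
        occ_ad = list(range(T))
        occ_juv = [t for t in range(T)
                   if not (s == fi and scenario.years[t] in flood_years)]
        for n, occs, a in ((n_ad, occ_ad, 0), (n_juv, occ_juv, 1)):
            n = int(round(n * scale))
            q, rmd = divmod(n, len(occs))
            for j, t in enumerate(occs):
                out[t, s, a] = q + (1 if j < rmd else 0)
    return out


def simulate_histories(truth, scenario, cohorts=None, seed=0):
    """Simulate encounter histories under the generating model.

    For each released bird, each interval applies survival (age-, stratum-
    and covariate-specific), then movement, then detection at the next
    occasion.  Returns (Histories, OccasionCovariates).
    """
    rng = np.random.default_rng(seed)
    if cohorts is None:
        cohorts = default_cohorts(scenario)
    T, S = len(scenario.years), len(scenario.strata)
    fi = scenario.strata.index(scenario.flow_stratum)

    release, strat0, juv_first = [], [], []
    for t in range(T):
        for s in range(S):
            for a in range(2):
                n = int(cohorts[t, s, a])
                release += [t] * n
                strat0 += [s] * n
                juv_first += [a == 1] * n
    release = np.array(release)
    strat0 = np.array(strat0)
    juv_first = np.array(juv_first)
    n = release.size

    hatch = np.zeros(n)
    band = np.zeros(n)
    for s, name in enumerate(scenario.strata):
        sd, (lo, hi), bmu, bsd, bmax = _PHENOLOGY[name]
        m = juv_first & (strat0 == s)
        k = int(m.sum())
        hatch[m] = np.clip(rng.normal(0.0, sd, k), lo, hi)
        band[m] = np.clip(np.round(rng.normal(bmu, bsd, k)), 0, bmax)

    psi = truth.psi_matrices(scenario)
    codes = np.zeros((n, T), dtype=np.int64)
    codes[np.arange(n), release] = strat0 + 1
    state = strat0.copy()
    alive = np.ones(n, dtype=bool)

    for t in range(T - 1):
        act = alive & (release <= t)
        if not np.any(act):
            continue
        juv = juv_first & (release == t)
        a_idx = juv.astype(int)
        eta = logit(truth.phi_cell[a_idx, state])
        flow_here = state == fi
        if scenario.hf_flag[t]:
            eta = eta + truth.phi_high_flow * flow_here
        if scenario.posthf_flag[t]:
            eta = eta + truth.phi_post_high_flow * flow_here
        eta = eta + juv * (truth.hatch_slope * hatch + truth.band_age_slope * band)
        phi = expit(eta)
        if t in scenario.flood_fix_intervals:      # structural zero
            phi = np.where(juv & flow_here, 0.0, phi)
        alive = alive & np.where(act, rng.random(n) < phi, True)

        act = alive & (release <= t)
        rows = psi[a_idx, t, state]                # [n, S]
        u = rng.random(n)
        dest = np.argmax(u[:, None] < np.cumsum(rows, axis=1), axis=1)
        state = np.where(act, dest, state)

        p_det = truth.p_cell[a_idx, state]
        seen = act & (rng.random(n) < p_det)
        codes[seen, t + 1] = state[seen] + 1

    recs = [EncounterHistory(
        bird_id=f"b{i:05d}", codes=tuple(codes[i]),
        age_class_at_first=JUVENILE if juv_first[i] else ADULT,
        hatch_day=float(hatch[i]) if juv_first[i] else 0.0,
        band_age=float(band[i]) if juv_first[i] else 0.0)
        for i in range(n)]
    return Histories(recs, scenario.strata), scenario.covariates()


def write_fixtures(outdir, hist, cov, seed, truth=None):
    """Write the encounter and covariate CSVs plus a manifest."""
    import os
    os.makedirs(outdir, exist_ok=True)
    hist.to_csv(os.path.join(outdir, "encounters.csv"), years=cov.years)
    cov.to_dataframe().to_csv(os.path.join(outdir, "covariates.csv"),
                              index=False)
    hist.to_inp(os.path.join(outdir, "encounters.inp"))
    manifest = {"seed": int(seed), "n_birds": hist.n_birds,
                "strata": hist.stratum_names}
    if truth is not None:
        manifest["truth"] = {
            "phi_cell": truth.phi_cell.tolist(),
            "p_cell": truth.p_cell.tolist(),
            "psi": [truth.psi_intercept, truth.psi_age, truth.psi_distance,
                    truth.psi_hf_emigration, truth.psi_hf_immigration,
                    truth.psi_posthf_immigration],
            "hatch_slope": truth.hatch_slope,
            "band_age_slope": truth.band_age_slope}
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


# ---------------------------------------------------------------------------
# Canonical PVA scenario
# ---------------------------------------------------------------------------

def canonical_pva_dict():
    """The frozen canonical PVA scenario as a plain dict."""
    text = (importlib.resources.files("plovermeta") / "data"
            / "canonical_study.json").read_text()
    return json.loads(text)


def _apply_override(doc, path, value):
    keys = path.split(".")
    node = doc
    for k in keys[:-1]:
        if isinstance(node, list):
            node = next((x for x in node if x.get("name") == k), None)
            if node is None:
                raise KeyError(path)
        elif k in node:
            node = node[k]
        else:
            raise KeyError(path)
    last = keys[-1]
    if isinstance(node, list):
        raise KeyError(path)
    if last not in node:
        raise KeyError(path)
    node[last] = value


def pva_fixture(overrides=None):
    """Canonical PVA config with dotted-path overrides applied.

    Example: ``pva_fixture({"replicates": 10,
    "subpops.M1F.flood_probability": 0.0})``.
    """
    doc = canonical_pva_dict()
    for path, value in (overrides or {}).items():
        _apply_override(doc, path, value)
    return config_from_dict(doc)
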