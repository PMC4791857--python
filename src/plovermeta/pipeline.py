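"""Pipeline orchestration, demographic formulas and report tables.

Runs simulate -> fit -> select -> average -> PVA -> report from a single
master seed (hierarchically split per stage with numpy's SeedSequence so
stages can be re-run independently), and implements the small reproductive
output arithmetic behind the per-subpopulation summary tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import encounter, pva, synth

log = logging.getLogger("plovermeta")


@dataclass
class ReproductiveOutputInputs:
    """Components of per-pair reproductive output."""

    clutch_size: float = 3.73       # eggs per nesting attempt
    female_success: float = 0.0     # P(a female has a successful nest)
    chick_survival: float = 0.0     # P(chick survives to fledge)

    def __post_init__(self):
        if self.clutch_size <= 0:
            raise ValueError("clutch size must be positive")
        for p in (self.female_success, self.chick_survival):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


def chicks_per_pair(inputs):
    """Chicks fledged per pair = clutch size x female success x chick
    survival to fledge (female success absorbs re-nesting after failures)."""
    return inputs.clutch_size * inputs.female_success * inputs.chick_survival


def mean_reproductive_output(values_by_subpop, decimals=2):
    """Arithmetic mean of yearly chicks-fledged/pair per subpopulation,
    rounded to report precision."""
    out = {}
    for name, values in values_by_subpop.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"no yearly values for {name!r}")
        out[name] = round(float(v.mean()), decimals)
    return out


def reproductive_output_table(scenario=None, decimals=2):
    """Per-year reproductive output table with the recomputed mean row."""
    scenario = scenario or synth.study_scenario()[1]
    df = pd.DataFrame(scenario.success, columns=scenario.strata,
                      index=scenario.years[:-1])
    means = mean_reproductive_output(
        {s: df[s].values for s in scenario.strata}, decimals)
    df.loc["Mean"] = [means[s] for s in scenario.strata]
    return df


@dataclass
class ReportBundle:
    ranked_models: pd.DataFrame = None
    coefficients: pd.DataFrame = None
    averaged_rates: pd.DataFrame = None
    reproductive_output: pd.DataFrame = None
    pva_summary: dict = None

    def write(self, outdir):
        os.makedirs(outdir, exist_ok=True)
        for name, df in (("ranked_models", self.ranked_models),
                         ("coefficients", self.coefficients),
                         ("averaged_rates", self.averaged_rates),
                         ("reproductive_output", self.reproductive_output)):
            if df is not None:
                df.to_csv(os.path.join(outdir, f"{name}.csv"))
        if self.pva_summary is not None:
            with open(os.path.join(outdir, "pva_summary.json"), "w") as fh:
                json.dump(self.pva_summary, fh, indent=1, sort_keys=True)


DEFAULT_CONFIG = {
    "stages": ["simulate", "fit", "pva", "report"],
    "chat": 1.0,
    "cohort_scale": 1.0,
    "pva_overrides": {},
    "candidate_models": "reduced",
}


def _stage_seed(master_seed, stage):
    order = ["simulate", "fit", "pva", "report"]
    ss = np.random.SeedSequence(master_seed).spawn(len(order))
    return ss[order.index(stage)]


def _reduced_candidates(fixes):
    """A small representative candidate set around the study's top model."""
    phi_top = ("intercept", "age", "sub", "age:sub", "hatch", "band_age",
               "high_flow", "post_high_flow")
    p_top = ("intercept", "age", "sub", "age:sub")
    flow = ("hf_emigration", "hf_immigration", "posthf_immigration")
    psis = {
        "age+distance+flow": ("intercept", "age", "distance") + flow,
        "age+distance": ("intercept", "age", "distance"),
        "age": ("intercept", "age"),
        "dot": ("intercept",),
    }
    return [encounter.ModelSpec(phi=phi_top, p=p_top, psi=ps, fixed=fixes,
                                label=f"phi(top) p(top) psi({nm})")
            for nm, ps in psis.items()]


def run_pipeline(config=None, seed=0, outdir="results"):
    """Execute the requested stages under one master seed; returns the
    ReportBundle and writes artifacts plus a provenance log."""
    cfg = dict(DEFAULT_CONFIG)
    if isinstance(config, str):
        with open(config) as fh:
            cfg.update(json.load(fh))
    elif config:
        cfg.update(config)
    stages = cfg["stages"]
    os.makedirs(outdir, exist_ok=True)
    bundle = ReportBundle()
    truth, scenario = synth.study_scenario()
    hist = cov = None

    if "simulate" in stages:
        sseed = _stage_seed(seed, "simulate")
        log.info("simulate: cohort scale %.2f", cfg["cohort_scale"])
        cohorts = synth.default_cohorts(scenario, cfg["cohort_scale"])
        hist, cov = synth.simulate_histories(
            truth, scenario, cohorts, seed=sseed.generate_state(1)[0] % 2**31)
        synth.write_fixtures(os.path.join(outdir, "fixtures"), hist, cov,
                             seed, truth)

    if "fit" in stages:
        if hist is None:
            raise RuntimeError("fit stage requires the simulate stage")
        dist = scenario.distances
        fixes = encounter.mandatory_fixes(scenario.flow_stratum,
                                          scenario.flood_fix_intervals)
        cands = _reduced_candidates(fixes)
        log.info("fit: %d candidate models", len(cands))
        fits = [encounter.fit(sp, hist, cov, dist, chat=cfg["chat"])
                for sp in cands]
        ms = encounter.rank_and_weight(fits)
        bundle.ranked_models = ms.table()
        bundle.coefficients = encounter.wald(ms.best)
        rows = []
        for age in (encounter.ADULT, encounter.JUVENILE):
            for origin in scenario.strata:
                for dest in scenario.strata:
                    if origin == dest:
                        continue
                    est, se = encounter.model_average(
                        ms, "psi", {"origin": origin, "dest": dest,
                                    "interval": 0, "age": age}, cov, dist)
                    rows.append({"age": age, "origin": origin, "dest": dest,
                                 "estimate": round(est, 2),
                                 "unconditional_se": round(se, 3)})
        bundle.averaged_rates = pd.DataFrame(rows)
        ms.to_json(os.path.join(outdir, "model_results.json"))

    if "pva" in stages:
        pseed = int(_stage_seed(seed, "pva").generate_state(1)[0] % 2**31)
        pcfg = synth.pva_fixture(cfg["pva_overrides"])
        log.info("pva: %d replicates x %d years", pcfg.replicates, pcfg.horizon)
        res = pva.run_pva(pcfg, seed=pseed)
        lambdas = {}
        for sp in pcfg.subpops:
            lambdas[sp.name] = round(pva.deterministic_lambda(
                1.0 - sp.adult_mortality.baseline,
                1.0 - sp.juvenile_mortality.baseline,
                sp.fecundity_baseline), 2)
        bundle.pva_summary = res.summary(lambdas)
        with open(os.path.join(outdir, "pva_summary.json"), "w") as fh:
            json.dump(bundle.pva_summary, fh, indent=1, sort_keys=True)
        res.trajectories().to_csv(os.path.join(outdir, "trajectories.csv"),
                                  index=False)

    if "report" in stages:
        bundle.reproductive_output = reproductive_output_table(scenario)
        bundle.write(outdir)

    provenance = {
        "seed": int(seed), "stages": stages,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "numpy": np.__version__, "python": platform.python_version(),
    }
    with open(os.path.join(outdir, "provenance.json"), "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return bundle
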