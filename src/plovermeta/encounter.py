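"""Multistate (Arnason-Schwarz) mark-recapture models with covariates.

Fits apparent survival (phi), resight (p) and transition (psi) probabilities
to encounter histories over S strata (here: subpopulations), using a
design-matrix linear predictor for each parameter class:

* logit link for phi and p;
* multinomial-logit link for psi with "remain in the current stratum" as the
  reference category, which guarantees that each origin's transition row
  (including the stay probability) sums to one under arbitrary covariates.

The likelihood of a history is computed by a forward pass over the hidden
state space (S strata plus an absorbing dead state), conditioning on the
first release.  Model selection uses QAICc with Akaike weights, and real
estimates can be model-averaged with unconditional standard errors.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

ADULT = "adult"
JUVENILE = "juvenile"

# Terms accepted per parameter class.  Interaction terms ("a:b") contribute
# only the product columns; main effects are listed separately, as in the
# model notation of the source tables.
_SHARED_TERMS = {"intercept", "age", "sub", "year", "age:sub", "age:year",
                 "sub:year", "age:sub:year", "success", "age:success"}
_PHI_TERMS = _SHARED_TERMS | {"hatch", "band_age", "high_flow", "post_high_flow"}
_P_TERMS = _SHARED_TERMS
_PSI_TERMS = _SHARED_TERMS | {"distance", "hf_emigration", "hf_immigration",
                              "posthf_immigration"}
_VALID_TERMS = {"phi": _PHI_TERMS, "p": _P_TERMS, "psi": _PSI_TERMS}


@dataclass
class EncounterHistory:
    """One bird's per-occasion state codes plus individual covariates.

    ``codes[t]`` is 0 when the bird was unseen at occasion ``t`` and the
    1-based stratum index otherwise.  ``hatch_day`` is season-relative
    (deviation in days from the stratum mean hatch date) and ``band_age``
    is age at banding in days; both are 0 for adults.
    """

    bird_id: str
    codes: tuple
    age_class_at_first: str = ADULT
    hatch_day: float = 0.0
    band_age: float = 0.0
    frequency: int = 1

    def __post_init__(self):
        if not any(c > 0 for c in self.codes):
            raise ValueError(f"history {self.bird_id!r} has no sighting")
        if self.frequency < 1:
            raise ValueError("frequency must be >= 1")
        if self.age_class_at_first not in (ADULT, JUVENILE):
            raise ValueError(f"unknown age class {self.age_class_at_first!r}")
        if self.age_class_at_first == ADULT and (self.hatch_day or self.band_age):
            raise ValueError("adults carry the reference value 0 for "
                             "hatch_day and band_age")


class Histories:
    """Vectorised container of encounter histories.

    Identical rows (codes, age class, covariates) are aggregated with a
    frequency count so the likelihood is evaluated once per unique history.
    """

    def __init__(self, records, stratum_names):
        self.stratum_names = list(stratum_names)
        S = len(self.stratum_names)
        key = {}
        for r in records:
            codes = tuple(int(c) for c in r.codes)
            if max(codes) > S:
                raise ValueError(
                    f"history {r.bird_id!r} uses stratum code {max(codes)} "
                    f"but only {S} strata are declared")
            k = (codes, r.age_class_at_first, float(r.hatch_day), float(r.band_age))
            key[k] = key.get(k, 0) + r.frequency
        rows = sorted(key.items())
        self.codes = np.array([k[0] for k, _ in rows], dtype=np.int64)
        self.juvenile_first = np.array([k[1] == JUVENILE for k, _ in rows])
        self.hatch = np.array([k[2] for k, _ in rows])
        self.band = np.array([k[3] for k, _ in rows])
        self.freq = np.array([f for _, f in rows], dtype=np.int64)
        self.release = np.argmax(self.codes > 0, axis=1)
        self.n, self.T = self.codes.shape
        self.S = S

    @property
    def n_birds(self):
        return int(self.freq.sum())

    def juvenile_at(self):
        """[n, T-1] flag: juvenile rates apply only to the first interval
        after a juvenile's release (age is a time-varying state)."""
        t = np.arange(self.T - 1)
        return self.juvenile_first[:, None] & (t[None, :] == self.release[:, None])

    # -- effective sample size and saturated likelihood ------------------

    def effective_sample_size(self):
        """Release events: every detection at occasions 1..T-1 exposes the
        bird to a further interval and counts once."""
        det = (self.codes[:, :-1] > 0).sum(axis=1)
        return int((self.freq * det).sum())

    def saturated_nll(self):
        """Saturated multinomial log-likelihood, grouped by release cohort
        (release occasion, release stratum, age class, covariate values)."""
        rel_strat = self.codes[np.arange(self.n), self.release]
        cohort = {}
        for i in range(self.n):
            ck = (int(self.release[i]), int(rel_strat[i]),
                  bool(self.juvenile_first[i]), float(self.hatch[i]),
                  float(self.band[i]))
            cohort.setdefault(ck, []).append(i)
        nll = 0.0
        for idx in cohort.values():
            f = self.freq[idx].astype(float)
            nll -= float(np.sum(f * np.log(f / f.sum())))
        return nll

    # -- I/O -------------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df, stratum_names):
        ycols = sorted(c for c in df.columns if c.startswith("y"))
        recs = []
        for _, row in df.iterrows():
            juv = str(row["age_class_first"]) == JUVENILE
            recs.append(EncounterHistory(
                bird_id=str(row["bird_id"]),
                codes=tuple(int(row[c]) for c in ycols),
                age_class_at_first=JUVENILE if juv else ADULT,
                hatch_day=float(row.get("hatch_day", 0.0)) if juv else 0.0,
                band_age=float(row.get("band_age", 0.0)) if juv else 0.0,
                frequency=int(row.get("frequency", 1))))
        return cls(recs, stratum_names)

    @classmethod
    def read_csv(cls, path, stratum_names):
        return cls.from_dataframe(pd.read_csv(path), stratum_names)

    def to_dataframe(self, years=None):
        T = self.T
        years = list(years) if years is not None else list(range(T))
        out = {"bird_id": [f"h{i:05d}" for i in range(self.n)],
               "age_class_first": np.where(self.juvenile_first, JUVENILE, ADULT),
               "hatch_day": self.hatch, "band_age": self.band,
               "frequency": self.freq}
        for j, y in enumerate(years):
            out[f"y{y}"] = self.codes[:, j]
        return pd.DataFrame(out)

    def to_csv(self, path, years=None):
        self.to_dataframe(years).to_csv(path, index=False)

    def to_inp(self, path):
        """MARK-style .inp export: stratum letters, frequency, ';'."""
        letters = "ABCDEFGH"
        with open(path, "w") as fh:
            for i in range(self.n):
                hs = "".join("0" if c == 0 else letters[c - 1]
                             for c in self.codes[i])
                fh.write(f"{hs} {int(self.freq[i])};\n")


@dataclass
class OccasionCovariates:
    """Year x stratum reproductive success plus per-interval flow flags.

    Flags attach to intervals (year t -> t+1), not occasions: the high-flow
    flags mark the 2010->2011 interval and the post-high-flow flag marks
    2011->2012 in the canonical study design.
    """

    years: list
    stratum_names: list
    success: np.ndarray            # [T-1, S]: success in the year opening interval t
    hf_flag: np.ndarray            # [T-1] high-flow interval indicator
    posthf_flag: np.ndarray        # [T-1] post-high-flow interval indicator
    flow_stratum: str = "M1F"

    def __post_init__(self):
        self.success = np.asarray(self.success, dtype=float)
        self.hf_flag = np.asarray(self.hf_flag, dtype=float)
        self.posthf_flag = np.asarray(self.posthf_flag, dtype=float)
        ni = len(self.years) - 1
        if self.success.shape != (ni, len(self.stratum_names)):
            raise ValueError("success must be [n_intervals, n_strata]")
        if np.any(self.success < 0) or not np.all(np.isfinite(self.success)):
            raise ValueError("success must be finite and >= 0")
        for f in (self.hf_flag, self.posthf_flag):
            if f.shape != (ni,) or not np.all(np.isin(f, (0.0, 1.0))):
                raise ValueError("flow flags must be binary per interval")

    @property
    def flow_index(self):
        return self.stratum_names.index(self.flow_stratum)

    @classmethod
    def from_dataframe(cls, df, years, stratum_names, flow_stratum="M1F"):
        ni = len(years) - 1
        succ = np.zeros((ni, len(stratum_names)))
        hf = np.zeros(ni)
        post = np.zeros(ni)
        for _, row in df.iterrows():
            if int(row["year"]) not in years[:-1]:
                continue
            t = years.index(int(row["year"]))
            s = stratum_names.index(str(row["stratum"]))
            succ[t, s] = float(row["success"])
            hf[t] = max(hf[t], float(row["hf_emig"]), float(row["hf_immig"]))
            post[t] = max(post[t], float(row["posthf_immig"]))
        return cls(list(years), list(stratum_names), succ, hf, post, flow_stratum)

    def to_dataframe(self):
        rows = []
        for t, y in enumerate(self.years[:-1]):
            for s, name in enumerate(self.stratum_names):
                rows.append({"year": y, "stratum": name,
                             "success": self.success[t, s],
                             "hf_emig": int(self.hf_flag[t]),
                             "hf_immig": int(self.hf_flag[t]),
                             "posthf_immig": int(self.posthf_flag[t])})
        return pd.DataFrame(rows)


def distance_matrix(stratum_names, pair_km):
    """Symmetric pairwise distance matrix (km) from {(a, b): km} pairs."""
    S = len(stratum_names)
    D = np.zeros((S, S))
    for (a, b), km in pair_km.items():
        i, j = stratum_names.index(a), stratum_names.index(b)
        if km <= 0:
            raise ValueError("off-diagonal distances must be positive")
        D[i, j] = D[j, i] = float(km)
    if np.any(D[~np.eye(S, dtype=bool)] <= 0):
        raise ValueError("missing pairwise distance")
    return D


@dataclass(frozen=True)
class FixedParameter:
    """Fix a real parameter (probability scale) before the forward pass."""

    param: str                     # 'phi' | 'p' | 'psi'
    stratum: str                   # stratum (phi, p) or origin stratum (psi)
    interval: int                  # interval index (0-based)
    age_class: str                 # 'adult' | 'juvenile'
    value: float = 0.0
    destination: str | None = None   # psi only; None = all destinations

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("fixed value must lie in [0, 1]")


@dataclass
class ModelSpec:
    """Symbolic model structure per parameter class, plus fixed parameters."""

    phi: tuple = ("intercept",)
    p: tuple = ("intercept",)
    psi: tuple = ("intercept",)
    fixed: tuple = ()
    label: str = ""
    # manual adjustment to the free-coefficient count used by QAICc, for
    # structurally confounded or boundary coefficients (not auto-deducted)
    k_adjust: int = 0

    def __post_init__(self):
        self.phi, self.p, self.psi = tuple(self.phi), tuple(self.p), tuple(self.psi)
        self.fixed = tuple(self.fixed)
        for cls, terms in (("phi", self.phi), ("p", self.p), ("psi", self.psi)):
            for t in terms:
                if t not in _VALID_TERMS[cls]:
                    raise ValueError(f"unknown term {t!r} for class {cls!r}")
        if not self.label:
            self.label = (f"phi({'+'.join(self.phi)}) p({'+'.join(self.p)}) "
                          f"psi({'+'.join(self.psi)})")


def mandatory_fixes(flow_stratum="M1F", intervals=(2, 3)):
    """Juvenile survival at, and juvenile emigration out of, the flow-affected
    stratum are structurally zero for the intervals opening in the two
    high-flow years (no fledged chicks were produced there)."""
    out = []
    for t in intervals:
        out.append(FixedParameter("phi", flow_stratum, t, JUVENILE, 0.0))
        out.append(FixedParameter("psi", flow_stratum, t, JUVENILE, 0.0))
    return tuple(out)


# ---------------------------------------------------------------------------
# Design compilation
# ---------------------------------------------------------------------------

def _contrast_columns(cls, term, env):
    """Column arrays for one term.  Arrays broadcast against the class's
    parameter tensor: [n, T-1, S] for phi/p, [n, T-1, S, S] for psi."""
    S = env["S"]
    ni = env["n_intervals"]

    def base(name):
        if name == "age":
            return [("age", env["juv"])]
        if name == "sub":
            if cls == "psi":   # transition-pair factor (ordered pairs)
                pairs = [(r, s) for r in range(S) for s in range(S) if r != s]
                return [(f"pair{r}{s}",
                         env["origin_is"](r) * env["dest_is"](s))
                        for r, s in pairs[1:]]
            return [(f"sub{s}", env["stratum_is"](s)) for s in range(1, S)]
        if name == "year":
            return [(f"year{t}", env["interval_is"](t)) for t in range(1, ni)]
        if name == "success":
            return [("success", env["success"])]
        raise ValueError(name)

    if term == "intercept":
        return [("intercept", env["ones"])]
    if term == "hatch":
        return [("hatch", env["juv"] * env["hatch"])]
    if term == "band_age":
        return [("band_age", env["juv"] * env["band"])]
    if term == "distance":
        return [("distance", env["distance"])]
    if term == "high_flow":
        return [("high_flow", env["hf_phi"])]
    if term == "post_high_flow":
        return [("post_high_flow", env["posthf_phi"])]
    if term == "hf_emigration":
        return [("hf_emigration", env["hf_emig"])]
    if term == "hf_immigration":
        return [("hf_immigration", env["hf_immig"])]
    if term == "posthf_immigration":
        return [("posthf_immigration", env["posthf_immig"])]
    if ":" in term:
        parts = term.split(":")
        cols = [base(p) for p in parts]
        out = []
        for combo in itertools.product(*cols):
            name = ":".join(c[0] for c in combo)
            arr = combo[0][1]
            for _, a in combo[1:]:
                arr = arr * a
            out.append((name, arr))
        return out
    return base(term)


def _make_env(cls, hist, cov, dist):
    """Broadcastable covariate arrays for the full parameter tensor."""
    n, T, S = hist.n, hist.T, hist.S
    ni = T - 1
    juv = hist.juvenile_at().astype(float)
    fi = cov.flow_index
    tax = np.arange(ni)
    env = {"S": S, "n_intervals": ni}
    if cls in ("phi", "p"):
        shape_hint = (1, 1, 1)
        env["ones"] = np.ones(shape_hint)
        env["juv"] = juv[:, :, None]
        env["hatch"] = hist.hatch[:, None, None]
        env["band"] = hist.band[:, None, None]
        env["stratum_is"] = lambda s: (np.arange(S) == s).astype(float)[None, None, :]
        env["interval_is"] = lambda t: (tax == t).astype(float)[None, :, None]
        env["success"] = cov.success[None, :, :]
        env["hf_phi"] = (cov.hf_flag[:, None]
                         * (np.arange(S) == fi)[None, :])[None, :, :]
        env["posthf_phi"] = (cov.posthf_flag[:, None]
                             * (np.arange(S) == fi)[None, :])[None, :, :]
    else:
        env["ones"] = np.ones((1, 1, 1, 1))
        env["juv"] = juv[:, :, None, None]
        org = (np.arange(S)[:, None] * np.ones(S)[None, :])
        dst = (np.ones(S)[:, None] * np.arange(S)[None, :])
        env["origin_is"] = lambda r: (org == r).astype(float)[None, None, :, :]
        env["dest_is"] = lambda s: (dst == s).astype(float)[None, None, :, :]
        env["interval_is"] = lambda t: (tax == t).astype(float)[None, :, None, None]
        env["success"] = cov.success[None, :, :, None]          # origin's success
        env["distance"] = dist[None, None, :, :]
        off = 1.0 - np.eye(S)
        from_flow = (org == fi).astype(float) * off
        to_flow = (dst == fi).astype(float) * off
        env["hf_emig"] = (cov.hf_flag[None, :, None, None]
                          * from_flow[None, None, :, :])
        env["hf_immig"] = (cov.hf_flag[None, :, None, None]
                           * to_flow[None, None, :, :])
        env["posthf_immig"] = (cov.posthf_flag[None, :, None, None]
                               * to_flow[None, None, :, :])
    return env


@dataclass
class DesignSet:
    """Compiled design tensors mapping beta to every real parameter."""

    spec: ModelSpec
    hist: Histories
    X_phi: np.ndarray              # [n, T-1, S, k_phi]
    X_p: np.ndarray                # [n, T-1, S, k_p]
    X_psi: np.ndarray              # [n, T-1, S, S, k_psi]
    names: list
    slices: dict                   # class -> slice into beta
    fix_phi: list                  # (age_is_juv, interval, stratum, value)
    fix_p: list
    fix_psi: list                  # (age_is_juv, interval, origin, dest|None, value)

    @property
    def k(self):
        return len(self.names)

    def __post_init__(self):
        # contiguous 2D views for fast eta = X @ beta
        self._X2 = {"phi": np.ascontiguousarray(self.X_phi.reshape(-1, self.X_phi.shape[-1])),
                    "p": np.ascontiguousarray(self.X_p.reshape(-1, self.X_p.shape[-1])),
                    "psi": np.ascontiguousarray(self.X_psi.reshape(-1, self.X_psi.shape[-1]))}

    def fixed_masks(self):
        """Boolean masks (phi, p, psi-row) of real parameters that are fixed,
        resolved against each bird's time-varying age class."""
        if not hasattr(self, "_fixmasks"):
            hist = self.hist
            juv = hist.juvenile_at()
            mp = np.zeros(self.X_phi.shape[:3], bool)
            mq = np.zeros(self.X_p.shape[:3], bool)
            mr = np.zeros(self.X_psi.shape[:3], bool)   # whole-row psi fixes
            for is_juv, t, s, _ in self.fix_phi:
                mp[juv[:, t] == is_juv, t, s] = True
            for is_juv, t, s, _ in self.fix_p:
                mq[juv[:, t] == is_juv, t, s] = True
            for is_juv, t, r, d, _ in self.fix_psi:
                if d is None:
                    mr[juv[:, t] == is_juv, t, r] = True
            self._fixmasks = (mp, mq, mr)
        return self._fixmasks


def compile_design(spec, hist, cov, dist):
    """Compile a ModelSpec into design tensors over the real parameters.

    k equals the number of distinct free coefficients; fixed real parameters
    are applied as probability-scale overrides in the forward pass and carry
    no coefficients.
    """
    if len(cov.years) != hist.T:
        raise ValueError("covariates must cover all occasions")
    if dist.shape != (hist.S, hist.S):
        raise ValueError("distance matrix does not match stratum count")
    tensors, names, slices = {}, [], {}
    shapes = {"phi": (hist.n, hist.T - 1, hist.S),
              "p": (hist.n, hist.T - 1, hist.S),
              "psi": (hist.n, hist.T - 1, hist.S, hist.S)}
    for cls, terms in (("phi", spec.phi), ("p", spec.p), ("psi", spec.psi)):
        env = _make_env(cls, hist, cov, dist)
        cols = []
        for term in terms:
            cols.extend(_contrast_columns(cls, term, env))
        if not cols:
            raise ValueError(f"class {cls!r} needs at least one free "
                             "coefficient (all-fixed models are rejected)")
        X = np.stack([np.broadcast_to(a, shapes[cls]) for _, a in cols], axis=-1)
        start = len(names)
        names.extend(f"{cls}:{nm}" for nm, _ in cols)
        slices[cls] = slice(start, len(names))
        tensors[cls] = np.ascontiguousarray(X)

    fixes = {"phi": [], "p": [], "psi": []}
    for fx in spec.fixed:
        if fx.stratum not in hist.stratum_names:
            raise ValueError(f"fixed parameter references unknown stratum "
                             f"{fx.stratum!r}")
        if not 0 <= fx.interval < hist.T - 1:
            raise ValueError("fixed parameter references nonexistent interval")
        s = hist.stratum_names.index(fx.stratum)
        juv = fx.age_class == JUVENILE
        if fx.param == "psi":
            d = (hist.stratum_names.index(fx.destination)
                 if fx.destination else None)
            fixes["psi"].append((juv, fx.interval, s, d, fx.value))
        elif fx.param in ("phi", "p"):
            fixes[fx.param].append((juv, fx.interval, s, fx.value))
        else:
            raise ValueError(f"unknown parameter class {fx.param!r}")
    return DesignSet(spec, hist, tensors["phi"], tensors["p"], tensors["psi"],
                     names, slices, fixes["phi"], fixes["p"], fixes["psi"])


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def real_parameters(beta, design):
    """Back-transform beta to (phi, p, psi) probability tensors with fixed
    parameters applied."""
    beta = np.asarray(beta, dtype=float)
    hist = design.hist
    juv = hist.juvenile_at()

    eta_phi = (design._X2["phi"] @ beta[design.slices["phi"]]).reshape(
        design.X_phi.shape[:-1])
    eta_p = (design._X2["p"] @ beta[design.slices["p"]]).reshape(
        design.X_p.shape[:-1])
    if not (np.all(np.isfinite(eta_phi)) and np.all(np.isfinite(eta_p))):
        raise FloatingPointError("non-finite linear predictor")
    phi = expit(eta_phi)
    p = expit(eta_p)

    eta_psi = (design._X2["psi"] @ beta[design.slices["psi"]]).reshape(
        design.X_psi.shape[:-1])
    S = hist.S
    diag = np.eye(S, dtype=bool)
    eta_psi[:, :, diag] = 0.0     # "remain" is the reference category
    ex = np.exp(eta_psi - eta_psi.max(axis=-1, keepdims=True))
    psi = ex / ex.sum(axis=-1, keepdims=True)

    for is_juv, t, s, v in design.fix_phi:
        m = juv[:, t] == is_juv
        phi[m, t, s] = v
    for is_juv, t, s, v in design.fix_p:
        m = juv[:, t] == is_juv
        p[m, t, s] = v
    for is_juv, t, r, d, v in design.fix_psi:
        m = juv[:, t] == is_juv
        if d is None:   # fix all movement out of r; the stay class absorbs
            for dd in range(S):
                if dd != r:
                    psi[m, t, r, dd] = v
            psi[m, t, r, r] = 1.0 - v * (S - 1)
        else:
            old = psi[m, t, r, d].copy()
            other = 1.0 - old
            scale = np.where(other > 0, (1.0 - v) / np.where(other > 0, other, 1.0), 0.0)
            for dd in range(S):
                if dd != d:
                    psi[m, t, r, dd] = psi[m, t, r, dd] * scale
            psi[m, t, r, d] = v
    return phi, p, psi


def history_probabilities(hist, phi, p, psi):
    """Per-history probabilities from raw (phi, p, psi) tensors
    ([n, T-1, S], [n, T-1, S], [n, T-1, S, S]) via the forward pass."""
    return _forward(hist, phi, p, psi)


def _forward(hist, phi, p, psi, tape=None):
    """Forward pass over S live strata plus an absorbing dead state; the
    unobserved tail is handled by carrying the dead mass (chi recursion).
    When ``tape`` is a list the per-interval intermediates are stored for
    reverse-mode differentiation."""
    n, T, S = hist.n, hist.T, hist.S
    alpha = np.zeros((n, S))
    rel_strat = hist.codes[np.arange(n), hist.release] - 1
    alpha[np.arange(n), rel_strat] = 1.0
    dead = np.zeros(n)

    for t in range(T - 1):
        active = hist.release <= t
        trans = phi[:, t, :, None] * psi[:, t, :, :]
        live = np.einsum("ns,nsd->nd", alpha, trans)
        dead_new = dead + np.einsum("ns,ns->n", alpha, 1.0 - phi[:, t, :])
        code = hist.codes[:, t + 1]
        obs = code > 0
        unseen = live * (1.0 - p[:, t, :])
        seen = np.zeros_like(live)
        io = np.where(obs)[0]
        seen[io, code[io] - 1] = live[io, code[io] - 1] * p[io, t, code[io] - 1]
        new_alpha = np.where(obs[:, None], seen, unseen)
        new_dead = np.where(obs, 0.0, dead_new)
        if tape is not None:
            tape.append((alpha, dead, active, obs, io, code, trans, live))
        alpha = np.where(active[:, None], new_alpha, alpha)
        dead = np.where(active, new_dead, dead)

    prob = alpha.sum(axis=1) + dead
    if np.any(prob <= 0.0):
        first = hist.codes[prob <= 0.0][0]
        raise ValueError(f"history {tuple(first)} has zero probability under "
                         "the design (first nonzero code conflicts with a "
                         "fixed parameter or the model)")
    return prob


def multistate_nll(beta, design):
    """Negative log-likelihood: -sum(freq * log P(history | first release))."""
    phi, p, psi = real_parameters(beta, design)
    prob = _forward(design.hist, phi, p, psi)
    return float(-(design.hist.freq * np.log(prob)).sum())


def multistate_nll_grad(beta, design):
    """NLL and its exact gradient by reverse accumulation through the
    forward pass, the link functions and the design tensors.

    Requires any psi fixes to be whole-row (destination None), which covers
    the mandatory structural zeros; destination-specific psi fixes fall back
    to finite differences in :func:`fit`.
    """
    hist = design.hist
    if any(d is not None for _, _, _, d, _ in design.fix_psi):
        raise NotImplementedError("analytic gradient requires whole-row psi fixes")
    phi, p, psi = real_parameters(beta, design)
    tape = []
    prob = _forward(design.hist, phi, p, psi, tape)
    freq = hist.freq
    nll = float(-(freq * np.log(prob)).sum())

    n, T, S = hist.n, hist.T, hist.S
    b_alpha = np.tile((-freq / prob)[:, None], (1, S))
    b_dead = -freq / prob
    b_phi = np.zeros_like(phi)
    b_p = np.zeros_like(p)
    b_psi = np.zeros_like(psi)

    for t in range(T - 2, -1, -1):
        alpha, dead, active, obs, io, code, trans, live = tape[t]
        act = active
        b_live = np.zeros((n, S))
        b_dead_prev = np.zeros(n)
        b_deadinc = np.zeros(n)
        # observed branch: alpha_new[c] = live[c] * p[c]; dead_new = 0
        io = np.where(obs & act)[0]
        c = code[io] - 1
        b_live[io, c] += b_alpha[io, c] * p[io, t, c]
        b_p[io, t, c] += b_alpha[io, c] * live[io, c]
        # unobserved branch: alpha_new = live * (1 - p); dead_new = dead + deadinc
        un = act & ~obs
        b_live[un] += b_alpha[un] * (1.0 - p[un, t, :])
        b_p[un, t, :] -= b_alpha[un] * live[un]
        b_dead_prev[un] = b_dead[un]
        b_deadinc[un] = b_dead[un]
        # observed branch contributes nothing to previous dead
        # live = alpha @ (phi * psi); deadinc = alpha @ (1 - phi)
        b_live[~act] = 0.0
        bl = b_live
        b_trans = alpha[:, :, None] * bl[:, None, :]
        b_alpha_prev = np.einsum("nd,nsd->ns", bl, trans)
        b_alpha_prev += b_deadinc[:, None] * (1.0 - phi[:, t, :])
        b_phi[:, t, :] -= b_deadinc[:, None] * alpha
        b_phi[:, t, :] += np.einsum("nsd,nsd->ns", b_trans, psi[:, t, :, :])
        b_psi[:, t, :, :] += b_trans * phi[:, t, :, None]
        # inactive birds pass gradients straight through
        b_alpha = np.where(act[:, None], b_alpha_prev, b_alpha)
        b_dead = np.where(act, b_dead_prev, b_dead)

    # chain through links; fixed real parameters carry no gradient
    mfix_phi, mfix_p, mfix_psi_row = design.fixed_masks()
    g_eta_phi = b_phi * phi * (1.0 - phi)
    g_eta_phi[mfix_phi] = 0.0
    g_eta_p = b_p * p * (1.0 - p)
    g_eta_p[mfix_p] = 0.0
    # softmax rows: g_eta_d = psi_d * (b_d - sum_e b_e psi_e); diagonal eta
    # is the constant reference
    dot = np.einsum("ntrd,ntrd->ntr", b_psi, psi)
    g_eta_psi = psi * (b_psi - dot[..., None])
    diag = np.eye(S, dtype=bool)
    g_eta_psi[:, :, diag] = 0.0
    g_eta_psi[mfix_psi_row] = 0.0

    grad = np.zeros_like(np.asarray(beta, dtype=float))
    grad[design.slices["phi"]] = design._X2["phi"].T @ g_eta_phi.ravel()
    grad[design.slices["p"]] = design._X2["p"].T @ g_eta_p.ravel()
    grad[design.slices["psi"]] = design._X2["psi"].T @ g_eta_psi.ravel()
    return nll, grad


# ---------------------------------------------------------------------------
# Fitting, QAICc, ranking, averaging
# ---------------------------------------------------------------------------

def qaicc(nll, chat, k, ess):
    """QAICc = 2*nll/chat + 2k + 2k(k+1)/(ess - k - 1)."""
    if chat < 1.0:
        raise ValueError("chat must be >= 1")
    if ess <= k + 1:
        raise ValueError(f"effective sample size {ess} must exceed k + 1 = {k + 1}")
    return 2.0 * nll / chat + 2.0 * k + 2.0 * k * (k + 1) / (ess - k - 1)


@dataclass
class FitResult:
    label: str
    spec: ModelSpec
    design: DesignSet
    beta: np.ndarray
    se: np.ndarray
    neg_log_lik: float
    k: int
    ess: int
    chat: float
    qaicc: float
    deviance: float
    converged: bool
    vcov: np.ndarray = None

    def to_dict(self):
        return {"label": self.label, "beta": list(map(float, self.beta)),
                "se": [None if not np.isfinite(s) else float(s) for s in self.se],
                "names": self.design.names, "nll": self.neg_log_lik,
                "k": self.k, "ess": self.ess, "chat": self.chat,
                "qaicc": self.qaicc, "deviance": self.deviance,
                "converged": self.converged}


def _fd_hessian(fun, x, eps=1e-4):
    k = len(x)
    H = np.zeros((k, k))
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            if i == j:
                xp = x.copy(); xp[i] += eps
                xm = x.copy(); xm[i] -= eps
                H[i, i] = (fun(xp) - 2 * f0 + fun(xm)) / eps**2
            else:
                H[i, j] = H[j, i] = ((fun(xpp) - fun(xpm) - fun(xmp) + fun(xmm))
                                     / (4 * eps**2))
    return H


def fit(spec, hist, cov, dist, chat=1.0, n_starts=5, seed=0, gtol=1e-5,
        maxiter=500):
    """Fit one model by quasi-Newton minimisation of the multistate NLL.

    SEs come from the inverse observed information scaled by chat; a null
    start (beta = 0) is tried first, followed by random restarts if the
    optimiser fails to converge.  Non-convergence is flagged, not raised.
    """
    design = compile_design(spec, hist, cov, dist)
    k = design.k
    rng = np.random.default_rng(seed)
    analytic = not any(d is not None for *_, d, _ in design.fix_psi)

    def obj_grad(b):
        try:
            return multistate_nll_grad(b, design)
        except (FloatingPointError, ValueError):
            return 1e12, np.zeros(k)

    def obj(b):
        try:
            return multistate_nll(b, design)
        except (FloatingPointError, ValueError):
            return 1e12

    best = None
    starts = [np.zeros(k)] + [rng.normal(0, 0.5, k) for _ in range(n_starts)]
    for x0 in starts:
        if analytic:
            res = minimize(obj_grad, x0, method="BFGS", jac=True,
                           options={"gtol": gtol, "maxiter": maxiter})
        else:
            res = minimize(obj, x0, method="BFGS",
                           options={"gtol": gtol, "maxiter": maxiter})
        gsmall = np.all(np.isfinite(res.jac)) and np.abs(res.jac).max() < 1e-3
        ok = ((res.success or gsmall) and np.all(np.isfinite(res.x))
              and res.fun < 1e11)
        if best is None or (ok and not best[1]) or (ok == best[1] and res.fun < best[0].fun):
            best = (res, ok)
        if ok:
            break
    res, converged = best

    if analytic:   # Hessian as forward differences of the exact gradient
        eps = 1e-5
        g0 = obj_grad(res.x)[1]
        H = np.empty((k, k))
        for i in range(k):
            xp = res.x.copy()
            xp[i] += eps
            H[:, i] = (obj_grad(xp)[1] - g0) / eps
        H = 0.5 * (H + H.T)
    else:
        H = _fd_hessian(obj, res.x)
    se = np.full(k, np.nan)
    vcov = np.full((k, k), np.nan)
    try:
        cov_b = chat * np.linalg.inv(H)
        d = np.diag(cov_b)
        good = d > 0
        se[good] = np.sqrt(d[good])
        vcov = cov_b
    except np.linalg.LinAlgError:
        cov_b = chat * np.linalg.pinv(H)
        d = np.diag(cov_b)
        good = d > 0
        se[good] = np.sqrt(d[good])
        vcov = cov_b

    nll = float(res.fun)
    ess = hist.effective_sample_size()
    dev = 2.0 * (nll - hist.saturated_nll())
    k_eff = k + spec.k_adjust
    q = qaicc(nll, chat, k_eff, ess)
    return FitResult(spec.label, spec, design, res.x.copy(), se, nll, k_eff,
                     ess, chat, q, dev, bool(converged), vcov)


@dataclass
class ModelSet:
    fits: list
    delta_qaicc: np.ndarray
    weights: np.ndarray

    @property
    def best(self):
        return self.fits[0]

    def table(self):
        return pd.DataFrame({
            "model": [f.label for f in self.fits],
            "k": [f.k for f in self.fits],
            "delta_qaicc": np.round(self.delta_qaicc, 3),
            "deviance": [round(f.deviance, 3) for f in self.fits],
            "qaicc_weight": np.round(self.weights, 3),
            "qaicc": [round(f.qaicc, 3) for f in self.fits],
        })

    def to_json(self, path=None):
        obj = {"models": [f.to_dict() for f in self.fits],
               "delta_qaicc": list(map(float, self.delta_qaicc)),
               "weights": list(map(float, self.weights))}
        if path:
            with open(path, "w") as fh:
                json.dump(obj, fh, indent=1)
        return obj


def rank_and_weight(fits):
    """Rank by QAICc (ties: smaller k, then label) and attach Akaike weights."""
    if not fits:
        raise ValueError("at least one fit is required")
    fits = sorted(fits, key=lambda f: (f.qaicc, f.k, f.label))
    q = np.array([f.qaicc for f in fits])
    delta = q - q[0]
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return ModelSet(fits, delta, w)


def _profile_row(fit_result, cls, profile):
    """Design row for one real parameter under a covariate profile."""
    design = fit_result.design
    hist = design.hist
    S = len(hist.stratum_names)
    ni = hist.T - 1
    t = int(profile["interval"])
    juv = 1.0 if profile.get("age", ADULT) == JUVENILE else 0.0
    sname = profile.get("stratum", profile.get("origin"))
    s = hist.stratum_names.index(sname)
    env = {"S": S, "n_intervals": ni, "ones": 1.0, "juv": juv,
           "hatch": float(profile.get("hatch", 0.0)),
           "band": float(profile.get("band_age", 0.0))}
    cov, dist = profile["_cov"], profile["_dist"]
    fi = cov.flow_index
    env["interval_is"] = lambda tt: 1.0 if tt == t else 0.0
    if cls in ("phi", "p"):
        env["stratum_is"] = lambda ss: 1.0 if ss == s else 0.0
        env["success"] = cov.success[t, s]
        env["hf_phi"] = cov.hf_flag[t] * (s == fi)
        env["posthf_phi"] = cov.posthf_flag[t] * (s == fi)
    else:
        d = hist.stratum_names.index(profile["dest"])
        env["origin_is"] = lambda rr: 1.0 if rr == s else 0.0
        env["dest_is"] = lambda dd: 1.0 if dd == d else 0.0
        env["success"] = cov.success[t, s]
        env["distance"] = dist[s, d]
        off = s != d
        env["hf_emig"] = cov.hf_flag[t] * (s == fi) * off
        env["hf_immig"] = cov.hf_flag[t] * (d == fi) * off
        env["posthf_immig"] = cov.posthf_flag[t] * (d == fi) * off
    spec_terms = getattr(fit_result.spec, cls)
    row = []
    for term in spec_terms:
        row.extend(v for _, v in _contrast_columns(cls, term, env))
    return np.array(row, dtype=float)


def real_estimate(fit_result, cls, profile, cov, dist):
    """Real-scale estimate and delta-method SE for one parameter/profile."""
    profile = dict(profile, _cov=cov, _dist=dist)
    design = fit_result.design
    if cls == "psi":
        # multinomial logit: compute all destination etas for the origin
        origin = profile.get("origin", profile.get("stratum"))
        dest = profile["dest"]
        hist = design.hist
        S = len(hist.stratum_names)
        s = hist.stratum_names.index(origin)
        beta = fit_result.beta[design.slices["psi"]]
        V = fit_result.vcov[design.slices["psi"], design.slices["psi"]]
        rows, etas = {}, {}
        for dd_name in hist.stratum_names:
            if dd_name == origin:
                continue
            pr = dict(profile, dest=dd_name)
            rows[dd_name] = _profile_row(fit_result, "psi", pr)
            etas[dd_name] = float(rows[dd_name] @ beta)
        denom = 1.0 + sum(np.exp(e) for e in etas.values())
        if dest == origin:
            est = 1.0 / denom
            grad = sum(-np.exp(etas[d]) / denom * rows[d] for d in rows) * est
        else:
            est = np.exp(etas[dest]) / denom
            grad = rows[dest] * est
            for d in rows:
                grad = grad - rows[d] * est * (np.exp(etas[d]) / denom)
        var = float(grad @ V @ grad)
        return est, np.sqrt(max(var, 0.0))
    row = _profile_row(fit_result, cls, profile)
    beta = fit_result.beta[design.slices[cls]]
    V = fit_result.vcov[design.slices[cls], design.slices[cls]]
    eta = float(row @ beta)
    est = float(expit(eta))
    grad = row * est * (1.0 - est)
    var = float(grad @ V @ grad)
    return est, np.sqrt(max(var, 0.0))


def akaike_average(estimates, ses, weights):
    """Weighted average with the unconditional-SE formula:

    theta_bar = sum_i w_i theta_i;
    SE_u = sum_i w_i sqrt(var_i + (theta_i - theta_bar)^2)
    (conditional variance plus squared deviation from the average)."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    w = np.asarray(weights, dtype=float)
    avg = float(np.sum(w * est))
    se_u = float(np.sum(w * np.sqrt(se**2 + (est - avg) ** 2)))
    return avg, se_u


def model_average(modelset, cls, profile, cov, dist):
    """QAICc-weight model average of a real parameter with unconditional SE."""
    ests, ses = [], []
    for f in modelset.fits:
        e, s = real_estimate(f, cls, profile, cov, dist)
        ests.append(e)
        ses.append(s)
    return akaike_average(ests, ses, modelset.weights)


def wald(fit_result, z=1.96):
    """Per-coefficient estimate, SE, |beta/SE| and 95% CI table."""
    rows = []
    for name, b, s in zip(fit_result.design.names, fit_result.beta,
                          fit_result.se):
        ok = np.isfinite(s) and s > 0
        rows.append({"coefficient": name, "estimate": round(float(b), 3),
                     "se": round(float(s), 3) if ok else np.nan,
                     "t": round(abs(float(b) / float(s)), 3) if ok else np.nan,
                     "lcl": round(float(b - z * s), 3) if ok else np.nan,
                     "ucl": round(float(b + z * s), 3) if ok else np.nan,
                     "se_available": bool(ok)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequential model selection
# ---------------------------------------------------------------------------

FLOW_PSI_TERMS = ("hf_emigration", "hf_immigration", "posthf_immigration")


def substitute_psi_terms(terms):
    """Stage-4 substitution grammar for a transition structure.

    Every 'sub' becomes 'distance'; every 'year' slot is replaced by each of
    {success}, {flow dummies}, {flow dummies + success}; if the structure
    keeps 'age' and gains 'success', the age:success interaction is added.
    Returns the list of substituted term tuples (1 if no 'year' slot, else 3).
    """
    terms = list(terms)
    base = ["distance" if t == "sub" else t for t in terms
            if ":" not in t or not {"sub", "year"} & set(t.split(":"))]
    has_year = "year" in terms or any(
        "year" in t.split(":") for t in terms if ":" in t)
    has_age = "age" in terms

    def with_success(tt):
        tt = list(tt) + ["success"]
        if has_age:
            tt.append("age:success")
        return tt

    core = [t for t in base if t != "year"]
    if not has_year:
        return [tuple(dict.fromkeys(core))]
    variants = [with_success(core),
                core + list(FLOW_PSI_TERMS),
                with_success(core + list(FLOW_PSI_TERMS))]
    return [tuple(dict.fromkeys(v)) for v in variants]


def sequential_selection(hist, cov, dist, stages, chat=1.0, seed=0,
                         fit_kwargs=None):
    """Staged model selection: at each stage the lowest-QAICc structure is
    carried forward; the final stage's ranked ModelSet is returned.

    ``stages`` is a list of callables: stage(previous_best_spec or None) ->
    list of ModelSpec candidates.  An empty candidate list is an error.
    """
    fit_kwargs = fit_kwargs or {}
    best = None
    modelset = None
    for i, stage in enumerate(stages):
        cands = stage(best)
        if not cands:
            raise ValueError(f"stage {i} produced no candidate models")
        fits = [fit(sp, hist, cov, dist, chat=chat, seed=seed, **fit_kwargs)
                for sp in cands]
        modelset = rank_and_weight(fits)
        best = modelset.best.spec
    return modelset


def study_stages(delta_keep=4.0):
    """The four-stage catalogue of the canonical study design.

    1. resight structures (phi, psi maximal);
    2. survival structures;
    3. transition structures;
    4. biological-hypothesis substitutions (distance/success/flow for
       sub/year) crossed with flow/success augmentations of survival.
    Structures are additive combinations of age, sub and year plus the
    interactions; the maximal structure is the fully crossed cell-means
    model.
    """
    combos = [("age",), ("age", "sub"), ("age", "year"), ("age", "sub", "year"),
              ("age", "sub", "age:sub"), ("age", "year", "age:year"),
              ("age", "sub", "year", "age:sub", "age:year"),
              ("age", "sub", "year", "age:sub", "age:year", "sub:year",
               "age:sub:year")]
    maximal = ("intercept",) + combos[-1]
    fixes = mandatory_fixes()

    def stage_p(_):
        out = []
        for c in combos:
            # resight always controls for subpopulation search effort
            terms = ("intercept",) + c if "sub" in c else ("intercept", "sub") + c
            out.append(ModelSpec(
                phi=maximal + ("hatch", "band_age"), p=tuple(dict.fromkeys(terms)),
                psi=maximal, fixed=fixes, label=f"p({'+'.join(c)})"))
        return out

    def stage_phi(best):
        out = []
        for c in combos:
            out.append(ModelSpec(
                phi=("intercept",) + c + ("hatch", "band_age"), p=best.p,
                psi=maximal, fixed=fixes, label=f"phi({'+'.join(c)})"))
        return out

    def stage_psi(best):
        psis = [("intercept",)] + [("intercept",) + c for c in combos[:-1]] \
            + [maximal]
        return [ModelSpec(phi=best.phi, p=best.p, psi=ps, fixed=fixes,
                          label=f"psi({'+'.join(ps[1:]) or 'dot'})")
                for ps in psis]

    def stage_hypotheses(best):
        # in the full procedure every retained psi within delta_keep enters;
        # the carried-forward interface supplies only the best structure here
        phi_adds = [(), ("high_flow", "post_high_flow"), ("success",),
                    ("high_flow", "post_high_flow", "success")]
        out = []
        for ps in substitute_psi_terms(best.psi):
            for add in phi_adds:
                out.append(ModelSpec(
                    phi=tuple(dict.fromkeys(best.phi + add)), p=best.p,
                    psi=("intercept",) + ps if "intercept" not in ps else ps,
                    fixed=fixes,
                    label=f"phi(+{'+'.join(add) or 'base'}) "
                          f"psi({'+'.join(ps)})"))
        return out

    return [stage_p, stage_phi, stage_psi, stage_hypotheses]
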