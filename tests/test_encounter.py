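"""Unit and property tests for the multistate mark-recapture engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from plovermeta import encounter as enc
from conftest import make_setting, random_parameter_tensors
from oracle import history_probability


def _histories(code_tuples, names, **kw):
    recs = [enc.EncounterHistory(f"b{i}", c, **kw)
            for i, c in enumerate(code_tuples)]
    return enc.Histories(recs, names)


class TestDesignCompilation:
    @pytest.mark.parametrize("spec_kw,expected_k", [
        (dict(), 3),                                     # one coef per class
        (dict(phi=("intercept", "sub")), 5),             # two stratum contrasts
        (dict(psi=("intercept", "age", "distance", "hf_emigration",
                   "hf_immigration", "posthf_immigration")), 8),
    ])
    def test_coefficient_counts(self, spec_kw, expected_k):
        names, cov, D = make_setting(3, 6, hf_interval=2, post_interval=3)
        hist = _histories([(1, 1, 0, 0, 0, 0), (2, 0, 3, 0, 0, 0)], names)
        d = enc.compile_design(enc.ModelSpec(**spec_kw), hist, cov, D)
        assert d.k == expected_k

    def test_flow_psi_terms_contribute_six_coefficients(self):
        names, cov, D = make_setting(3, 6, hf_interval=2, post_interval=3)
        hist = _histories([(1, 1, 0, 0, 0, 0)], names)
        spec = enc.ModelSpec(psi=("intercept", "age", "distance",
                                  "hf_emigration", "hf_immigration",
                                  "posthf_immigration"))
        d = enc.compile_design(spec, hist, cov, D)
        assert sum(n.startswith("psi:") for n in d.names) == 6

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown term"):
            enc.ModelSpec(phi=("intercept", "moon_phase"))

    def test_fixed_parameter_on_missing_stratum_rejected(self):
        names, cov, D = make_setting(2, 3)
        hist = _histories([(1, 1, 0)], names)
        spec = enc.ModelSpec(fixed=(enc.FixedParameter(
            "phi", "nowhere", 0, enc.JUVENILE, 0.0),))
        with pytest.raises(ValueError, match="unknown stratum"):
            enc.compile_design(spec, hist, cov, D)

    def test_age_is_time_varying(self):
        """A bird released as a juvenile is juvenile for its first interval
        only, adult thereafter."""
        names, cov, D = make_setting(2, 4)
        hist = _histories([(0, 1, 1, 0)], names,
                          age_class_at_first=enc.JUVENILE, hatch_day=3.0,
                          band_age=1.0)
        juv = hist.juvenile_at()
        assert juv.tolist() == [[False, True, False]]


class TestLikelihood:
    def test_worked_two_strata_example(self):
        """phi=0.8, psi_AB=0.3, p=0.6: P(A A 0) = 0.336 * 0.52 = 0.17472."""
        names, cov, D = make_setting(2, 3)
        hist = _histories([(1, 1, 0)], names)
        d = enc.compile_design(enc.ModelSpec(), hist, cov, D)
        beta = np.array([logit(0.8), logit(0.6), np.log(0.3 / 0.7)])
        nll = enc.multistate_nll(beta, d)
        assert np.exp(-nll) == pytest.approx(0.17472, abs=1e-12)
        assert nll == pytest.approx(1.7446, abs=1e-4)

    def test_unseen_middle_occasion_matches_oracle(self):
        """History 'A 0 B' sums over the hidden occasion-2 stratum."""
        names, cov, D = make_setting(2, 3)
        hist = _histories([(1, 0, 2)], names)
        d = enc.compile_design(enc.ModelSpec(), hist, cov, D)
        beta = np.array([logit(0.8), logit(0.6), np.log(0.3 / 0.7)])
        phi = np.full((1, 2, 2), 0.8)
        p = np.full((1, 2, 2), 0.6)
        psi = np.broadcast_to([[0.7, 0.3], [0.3, 0.7]], (1, 2, 2, 2))
        expect = history_probability((1, 0, 2), phi[0], p[0], psi[0])
        assert np.exp(-enc.multistate_nll(beta, d)) == pytest.approx(
            expect, abs=1e-12)

    def test_certain_parameters_give_probability_one(self):
        names, cov, D = make_setting(2, 4)
        hist = _histories([(1, 1, 1, 1)], names)
        d = enc.compile_design(enc.ModelSpec(), hist, cov, D)
        beta = np.array([30.0, 30.0, -30.0])   # phi=1, p=1, stay=1
        assert enc.multistate_nll(beta, d) == pytest.approx(0.0, abs=1e-9)

    def test_forward_pass_matches_enumeration_on_random_draws(self):
        """Spot-check of the acceptance-level oracle equivalence."""
        rng = np.random.default_rng(5)
        names, cov, D = make_setting(3, 4)
        codes = [(1, 0, 0, 2), (2, 3, 0, 1), (0, 3, 0, 0), (1, 1, 1, 1)]
        hist = _histories(codes, names)
        for _ in range(10):
            phi, p, psi = random_parameter_tensors(rng, hist.n, 4, 3)
            probs = enc.history_probabilities(hist, phi, p, psi)
            for i in range(hist.n):
                expect = history_probability(tuple(hist.codes[i]),
                                             phi[i], p[i], psi[i])
                assert probs[i] == pytest.approx(expect, abs=1e-10)

    def test_gradient_matches_finite_differences(self, study_data):
        d = enc.compile_design(study_data["spec"], study_data["hist"],
                               study_data["cov"], study_data["dist"])
        rng = np.random.default_rng(2)
        b = study_data["beta_true"] + rng.normal(0, 0.2, d.k)
        nll, g = enc.multistate_nll_grad(b, d)
        assert nll == pytest.approx(enc.multistate_nll(b, d), rel=1e-12)
        eps = 1e-6
        for i in rng.choice(d.k, size=8, replace=False):
            e = np.zeros(d.k)
            e[i] = eps
            fd = (enc.multistate_nll(b + e, d)
                  - enc.multistate_nll(b - e, d)) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_psi_rows_sum_to_one_under_arbitrary_beta(self):
        names, cov, D = make_setting(3, 6, hf_interval=2, post_interval=3)
        hist = _histories([(1, 0, 2, 0, 0, 3)], names)
        spec = enc.ModelSpec(psi=("intercept", "age", "distance",
                                  "hf_emigration", "hf_immigration",
                                  "posthf_immigration"))
        d = enc.compile_design(spec, hist, cov, D)
        rng = np.random.default_rng(0)
        for _ in range(20):
            beta = rng.normal(0, 2, d.k)
            _, _, psi = enc.real_parameters(beta, d)
            assert np.allclose(psi.sum(axis=-1), 1.0, atol=1e-12)

    def test_fixed_parameters_forced_in_forward_pass(self):
        """The structural zeros override the linear predictor for the right
        age class, stratum and interval -- and only there."""
        names, cov, D = make_setting(3, 6, stratum_names=["HC", "M1F", "M2"],
                                     hf_interval=2, post_interval=3)
        hist = _histories([(0, 0, 2, 0, 0, 0)], names,
                          age_class_at_first=enc.JUVENILE)
        spec = enc.ModelSpec(fixed=enc.mandatory_fixes("M1F", (2, 3)))
        d = enc.compile_design(spec, hist, cov, D)
        beta = np.zeros(d.k)
        phi, _, psi = enc.real_parameters(beta, d)
        assert phi[0, 2, 1] == 0.0                      # juvenile interval
        assert phi[0, 3, 1] == pytest.approx(0.5)       # adult by then
        assert psi[0, 2, 1, 1] == 1.0                   # no emigration
        assert psi[0, 2, 1, 0] == 0.0
        assert psi[0, 0, 1, 1] != 1.0                   # other intervals free

    def test_all_fixed_model_rejected(self):
        names, cov, D = make_setting(2, 3)
        hist = _histories([(1, 1, 0)], names)
        spec = enc.ModelSpec(phi=())
        with pytest.raises(ValueError, match="at least one free"):
            enc.compile_design(spec, hist, cov, D)


class TestInformationCriterion:
    @pytest.mark.parametrize("nll,chat,k,ess,expected", [
        (100.0, 1.0, 5, 100, 200 + 10 + 60 / 94),
        (100.0, 2.0, 5, 100, 100 + 10 + 60 / 94),
        (123.4, 1.0, 0, 50, 246.8),
    ])
    def test_formula(self, nll, chat, k, ess, expected):
        assert enc.qaicc(nll, chat, k, ess) == pytest.approx(expected, abs=1e-9)

    def test_small_sample_guard(self):
        with pytest.raises(ValueError, match="must exceed"):
            enc.qaicc(10.0, 1.0, 9, 10)

    @given(nll=st.floats(1, 1e4), k=st.integers(1, 30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_aic_limit(self, nll, k):
        """QAICc -> AIC as ess -> infinity with chat = 1."""
        assert enc.qaicc(nll, 1.0, k, 10**9) == pytest.approx(
            2 * nll + 2 * k, rel=1e-6)


class _StubFit:
    def __init__(self, label, q, k):
        self.label, self.qaicc, self.k = label, q, k


class TestRankingAndAveraging:
    def test_equal_models_share_weight(self):
        ms = enc.rank_and_weight([_StubFit("a", 10.0, 2), _StubFit("b", 10.0, 2)])
        assert np.allclose(ms.weights, [0.5, 0.5])
        assert ms.delta_qaicc[0] == 0.0

    def test_delta_two_weights(self):
        ms = enc.rank_and_weight([_StubFit("a", 10.0, 2), _StubFit("b", 12.0, 3)])
        e = np.exp(-1.0)
        assert ms.weights == pytest.approx([1 / (1 + e), e / (1 + e)], abs=1e-12)

    def test_ties_broken_by_k_then_label(self):
        ms = enc.rank_and_weight([_StubFit("z", 5.0, 3), _StubFit("a", 5.0, 2),
                                  _StubFit("b", 5.0, 2)])
        assert [f.label for f in ms.fits] == ["a", "b", "z"]

    @given(st.lists(st.floats(0, 500), min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weights_sum_to_one_and_shift_invariant(self, qs):
        fits = [_StubFit(str(i), q, 1) for i, q in enumerate(qs)]
        ms = enc.rank_and_weight(fits)
        assert np.sum(ms.weights) == pytest.approx(1.0, abs=1e-12)
        ms2 = enc.rank_and_weight(
            [_StubFit(str(i), q + 37.5, 1) for i, q in enumerate(qs)])
        assert np.allclose(sorted(ms.weights), sorted(ms2.weights), atol=1e-9)

    def test_single_model_average_is_identity(self):
        est, se = enc.akaike_average([0.42], [0.05], [1.0])
        assert (est, se) == (0.42, 0.05)

    def test_two_model_average(self):
        est, _ = enc.akaike_average([0.2, 0.4], [0.01, 0.01], [0.5, 0.5])
        assert est == pytest.approx(0.3)

    @given(st.integers(2, 8), st.integers(0, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_unconditional_se_dominates_conditional(self, m, seed):
        rng = np.random.default_rng(seed)
        est = rng.uniform(0, 1, m)
        se = rng.uniform(0.01, 0.3, m)
        w = rng.dirichlet(np.ones(m))
        _, se_u = enc.akaike_average(est, se, w)
        assert se_u >= np.sum(w * se) - 1e-12


class TestWald:
    def test_published_coefficient_ratios(self):
        """Distance and high-flow-emigration rows match the printed table."""
        fr = _wald_stub([-0.011, 1.690], [0.001, 0.256])
        tab = enc.wald(fr)
        assert tab.loc[0, "t"] == 11.000
        assert tab.loc[1, "t"] == 6.602
        assert (tab.loc[1, "lcl"], tab.loc[1, "ucl"]) == (1.188, 2.192)

    def test_zero_beta(self):
        tab = enc.wald(_wald_stub([0.0], [0.4]))
        assert tab.loc[0, "t"] == 0.0
        assert tab.loc[0, "lcl"] == -tab.loc[0, "ucl"]

    def test_missing_se_flagged(self):
        tab = enc.wald(_wald_stub([1.0], [np.nan]))
        assert not tab.loc[0, "se_available"]


def _wald_stub(betas, ses):
    class _D:
        names = [f"c{i}" for i in range(len(betas))]
    class _F:
        design = _D()
        beta = np.array(betas)
        se = np.array(ses)
    return _F()


class TestSequentialSelection:
    def test_substitution_grammar_with_sub_and_year(self):
        """A psi structure holding both 'sub' and 'year' expands to exactly
        the distance + {success, flow, flow+success} variants."""
        variants = enc.substitute_psi_terms(("intercept", "age", "sub", "year"))
        assert len(variants) == 3
        for v in variants:
            assert "distance" in v and "sub" not in v and "year" not in v
        flow = set(enc.FLOW_PSI_TERMS)
        assert sum(flow <= set(v) for v in variants) == 2
        assert sum("success" in v for v in variants) == 2
        assert all("age:success" in v for v in variants if "success" in v)

    def test_substitution_without_year_is_single_variant(self):
        variants = enc.substitute_psi_terms(("intercept", "sub"))
        assert variants == [("intercept", "distance")]

    def test_single_candidate_stages_compose(self, study_data):
        hist, cov, D = (study_data["hist"], study_data["cov"],
                        study_data["dist"])
        s1 = lambda prev: [enc.ModelSpec(label="s1")]
        s2 = lambda prev: [enc.ModelSpec(phi=prev.phi, p=("intercept", "age"),
                                         label="s2")]
        ms = enc.sequential_selection(hist, cov, D, [s1, s2])
        assert ms.best.spec.p == ("intercept", "age")
        assert len(ms.fits) == 1

    def test_empty_stage_is_an_error(self, study_data):
        with pytest.raises(ValueError, match="no candidate"):
            enc.sequential_selection(study_data["hist"], study_data["cov"],
                                     study_data["dist"], [lambda prev: []])

    def test_distance_model_outranks_constant_on_distance_driven_data(
            self, study_data):
        """With a strong generating distance effect the psi(distance) model
        beats psi(.) decisively."""
        hist, cov, D = (study_data["hist"], study_data["cov"],
                        study_data["dist"])
        base = dict(phi=("intercept", "age"), p=("intercept", "sub"))
        m_dist = enc.ModelSpec(psi=("intercept", "distance"), label="dist",
                               **base)
        m_dot = enc.ModelSpec(psi=("intercept",), label="dot", **base)
        fits = [enc.fit(m, hist, cov, D) for m in (m_dist, m_dot)]
        ms = enc.rank_and_weight(fits)
        assert ms.best.label == "dist"
        assert ms.delta_qaicc[1] > 10


class TestFitting:
    def test_consistency_on_large_sample(self):
        """Fitting the generating model to a large simulated sample recovers
        the truth on the probability scale."""
        from plovermeta import synth
        truth, scen = synth.study_scenario()
        truth = synth.TruthParameters(
            phi_cell=truth.phi_cell, p_cell=truth.p_cell,
            hatch_slope=0.0, band_age_slope=0.0)
        cohorts = synth.default_cohorts(scen, scale=20000 / 2640)
        hist, cov = synth.simulate_histories(truth, scen, cohorts, seed=99)
        spec, _, _, _ = synth.generating_model()
        fr = enc.fit(spec, hist, scen.covariates(), scen.distances)
        assert fr.converged
        d = fr.design
        i = d.names.index("phi:intercept")
        from scipy.special import expit
        assert expit(fr.beta[i]) == pytest.approx(0.70, abs=0.02)
        j = d.names.index("psi:distance")
        assert fr.beta[j] == pytest.approx(-0.011, abs=0.002)

    def test_export_roundtrip_inp(self, tmp_path, study_data):
        hist = study_data["hist"]
        path = tmp_path / "x.inp"
        hist.to_inp(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == hist.n
        assert all(line.endswith(";") for line in lines)
        assert set("".join(l.split()[0] for l in lines)) <= set("ABC0")
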