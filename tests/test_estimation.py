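"""Censored likelihood, ML fitting, LRT, SIR, hazard ratios, half-lives."""

import math

import numpy as np
import pytest

from strokette import (
    CovariateProfile,
    HazardSpec,
    SubjectRecord,
    cumulative_hazard,
    fit,
    half_life,
    hazard_at,
    hazard_ratio_ci,
    lrt,
    ofv,
    sir_uncertainty,
)


def brute_force_ofv(data, spec):
    """Independent per-subject loop through the scalar public API."""
    loglik = 0.0
    for s in data:
        prof = CovariateProfile({k: s.covariates.values[k]
                                 for k in spec.covariate_coefficients})
        if s.event:
            loglik += math.log(hazard_at(spec, s.time, prof))
        loglik -= cumulative_hazard(spec, s.time, prof)
    return -2.0 * loglik


class TestOfv:
    def test_single_censored_subject(self):
        spec = HazardSpec("constant", ((0.0, 1.0),))
        data = [SubjectRecord(1, 2.0, 0)]
        assert ofv(data, spec) == pytest.approx(4.0, rel=1e-12)

    def test_single_event_subject(self):
        spec = HazardSpec("constant", ((0.0, 1.0),))
        data = [SubjectRecord(1, 1.0, 1)]
        # -2 (ln 1 - 1) = 2
        assert ofv(data, spec) == pytest.approx(2.0, rel=1e-12)

    def test_matches_brute_force_on_exponential_sample(self):
        rng = np.random.default_rng(42)
        h0 = 0.3
        spec = HazardSpec("constant", ((0.0, h0),))
        data = []
        for i in range(50):
            t = rng.exponential(1 / h0)
            ev = int(t <= 4.0)
            data.append(SubjectRecord(i, min(t, 4.0), ev))
        # analytic exponential log density / log survival, subject by subject
        loglik = sum(
            (math.log(h0) - h0 * s.time) if s.event else (-h0 * s.time)
            for s in data
        )
        assert ofv(data, spec) == pytest.approx(-2 * loglik, rel=1e-12)
        assert ofv(data, spec) == pytest.approx(brute_force_ofv(data, spec),
                                                rel=1e-12)

    def test_matches_brute_force_with_covariates(self, dm_final_spec):
        rng = np.random.default_rng(7)
        data = [
            SubjectRecord(i, float(rng.uniform(0.05, 7.37)),
                          int(rng.uniform() < 0.3),
                          CovariateProfile({"IHD": int(rng.uniform() < 0.2),
                                            "HPLD": int(rng.uniform() < 0.4)}))
            for i in range(100)
        ]
        assert ofv(data, dm_final_spec) == pytest.approx(
            brute_force_ofv(data, dm_final_spec), rel=1e-12)


class TestFit:
    def test_constant_recovery_within_three_se(self, constant_cohort):
        res = fit(constant_cohort, HazardSpec("constant", ((0.0, 1.0),)))
        assert res.converged
        h = res.estimates["h0[0]"]
        se = h / math.sqrt(res.n_events)  # exponential-model asymptotics
        assert abs(h - 0.2) < 3 * se

    def test_all_censored_rejected(self):
        data = [SubjectRecord(i, 1.0, 0) for i in range(5)]
        with pytest.raises(ValueError, match="censored"):
            fit(data, HazardSpec("constant", ((0.0, 1.0),)))

    def test_adding_null_covariate_never_raises_ofv(self, constant_cohort):
        rng = np.random.default_rng(1)
        noise = rng.uniform(size=len(constant_cohort)) < 0.5
        data = [
            SubjectRecord(s.id, s.time, s.event,
                          CovariateProfile({"NOISE": int(z)}))
            for s, z in zip(constant_cohort, noise)
        ]
        base = fit(data, HazardSpec("constant", ((0.0, 1.0),)))
        full = fit(data, HazardSpec("constant", ((0.0, 1.0),),
                                    covariate_coefficients={"NOISE": 0.0}),
                   start="template")
        assert full.ofv <= base.ofv + 1e-4

    def test_deterministic(self, constant_cohort):
        t = HazardSpec("constant", ((0.0, 1.0),))
        r1, r2 = fit(constant_cohort, t), fit(constant_cohort, t)
        assert r1.estimates == r2.estimates
        assert r1.ofv == r2.ofv


class TestLrt:
    @pytest.mark.parametrize("delta, expected", [(3.84, 0.05), (6.64, 0.01)])
    def test_stepwise_gate_values(self, delta, expected):
        assert lrt(100.0, 100.0 - delta, 1) == pytest.approx(expected,
                                                             abs=5e-4)

    def test_zero_drop_gives_p_one(self):
        assert lrt(50.0, 50.0, 1) == 1.0

    def test_negative_drop_beyond_tolerance_rejected(self):
        with pytest.raises(ValueError):
            lrt(50.0, 51.0, 1)
        # tiny optimizer noise is tolerated
        assert lrt(50.0, 50.00001, 1) == 1.0


class TestSir:
    def test_rse_agrees_with_exponential_asymptotics(self, constant_cohort):
        res = fit(constant_cohort, HazardSpec("constant", ((0.0, 1.0),)))
        sir = sir_uncertainty(constant_cohort, res, seed=99)
        asymptotic = 100.0 / math.sqrt(res.n_events)
        assert sir.rse_percent["h0[0]"] == pytest.approx(asymptotic, rel=0.20)
        lo, hi = sir.ci["h0[0]"]
        assert lo < res.estimates["h0[0]"] < hi

    def test_seed_determinism(self, constant_cohort):
        res = fit(constant_cohort, HazardSpec("constant", ((0.0, 1.0),)))
        a = sir_uncertainty(constant_cohort, res, seed=5,
                            n_proposal=400, n_resample=200)
        b = sir_uncertainty(constant_cohort, res, seed=5,
                            n_proposal=400, n_resample=200)
        assert a.rse_percent == b.rse_percent
        assert a.ci == b.ci

    def test_resample_larger_than_proposal_rejected(self, constant_cohort):
        res = fit(constant_cohort, HazardSpec("constant", ((0.0, 1.0),)))
        with pytest.raises(ValueError):
            sir_uncertainty(constant_cohort, res, n_proposal=100,
                            n_resample=200)


class TestHazardRatioCi:
    def test_published_ihd_row(self):
        hr, lo, hi = hazard_ratio_ci(0.876, 16.88)
        assert (round(hr, 2), round(lo, 2)) == (2.40, 1.80)
        assert hr == pytest.approx(math.exp(0.876), rel=1e-12)
        assert lo < hr < hi

    def test_null_coefficient(self):
        assert hazard_ratio_ci(0.0, 25.0) == (1.0, 1.0, 1.0)

    def test_protective_coefficient_keeps_ci_ordered(self):
        hr, lo, hi = hazard_ratio_ci(-0.835, 24.80)
        assert lo < hr < hi < 1.0

    def test_negative_rse_rejected(self):
        with pytest.raises(ValueError):
            hazard_ratio_ci(0.5, -1.0)


class TestHalfLife:
    def test_values(self):
        assert half_life(math.log(2)) == pytest.approx(1.0, rel=1e-12)
        assert half_life(1.58) == pytest.approx(0.4387, abs=1e-4)
        assert half_life(0.242) == pytest.approx(2.8642, abs=1e-4)

    def test_zero_shape_rejected(self):
        with pytest.raises(ValueError):
            half_life(0.0)


class TestSubjectRecord:
    @pytest.mark.parametrize("t, ev", [(0.0, 1), (-1.0, 0), (1.0, 2),
                                       (math.nan, 0)])
    def test_invalid_rows_rejected(self, t, ev):
        with pytest.raises(ValueError):
            SubjectRecord(1, t, ev)
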