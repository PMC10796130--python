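"""Hazard families: closed forms against quadrature, invariants, errors."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokette import (
    CovariateProfile,
    HazardSpec,
    cumulative_hazard,
    hazard_at,
    survival,
)

from conftest import quadrature_cumhaz, random_spec


class TestHazardAt:
    def test_constant_is_time_independent(self):
        spec = HazardSpec("constant", ((0.0, 0.5),))
        assert {hazard_at(spec, t) for t in (0.0, 0.3, 2.0, 7.37)} == {0.5}

    def test_piecewise_gompertz_closed_form(self, dm_base_spec):
        # h0 * exp(shape * t) on the first segment
        assert hazard_at(dm_base_spec, 0.25) == pytest.approx(
            0.356 * math.exp(1.58 * 0.25), rel=1e-12)
        assert hazard_at(dm_base_spec, 0.25) == pytest.approx(0.52844077, abs=1e-7)

    def test_covariate_multiplies_hazard(self, dm_final_spec):
        prof0 = CovariateProfile({"IHD": 0, "HPLD": 0})
        prof1 = CovariateProfile({"IHD": 1, "HPLD": 0})
        h1 = hazard_at(dm_final_spec, 0.25, prof1)
        assert h1 == pytest.approx(1.26893181, abs=1e-7)
        # the multiplicative factor is the hazard ratio e^beta at any time
        for t in (0.1, 0.25, 1.0, 5.0):
            ratio = hazard_at(dm_final_spec, t, prof1) / \
                hazard_at(dm_final_spec, t, prof0)
            assert ratio == pytest.approx(math.exp(0.876), rel=1e-12)

    def test_segment_boundaries_are_half_open(self, dm_base_spec):
        # at exactly 0.5 y the second baseline applies; at 3 y the second shape
        assert hazard_at(dm_base_spec, 0.5) == pytest.approx(
            0.0023 * math.exp(1.58 * 0.5), rel=1e-12)
        assert hazard_at(dm_base_spec, 3.0) == pytest.approx(
            0.0023 * math.exp(0.242 * 3.0), rel=1e-12)

    @pytest.mark.parametrize("bad_t", [-1.0, -1e-9])
    def test_negative_time_rejected(self, dm_base_spec, bad_t):
        with pytest.raises(ValueError):
            hazard_at(dm_base_spec, bad_t)

    def test_weibull_undefined_at_zero(self):
        spec = HazardSpec("weibull", ((0.0, 1.0),), ((0.0, 0.5),))
        with pytest.raises(ValueError):
            hazard_at(spec, 0.0)
        assert hazard_at(spec, 4.0) == pytest.approx(2.0, rel=1e-12)

    def test_unknown_and_missing_covariates_rejected(self, dm_final_spec):
        with pytest.raises(KeyError):
            hazard_at(dm_final_spec, 1.0,
                      CovariateProfile({"IHD": 1, "HPLD": 0, "AF": 1}))
        with pytest.raises(KeyError):  # missing is an error, not 0
            hazard_at(dm_final_spec, 1.0, CovariateProfile({"IHD": 1}))

    def test_continuous_covariates_rejected(self):
        with pytest.raises(ValueError):
            CovariateProfile({"IHD": 0.5})


class TestCumulativeHazard:
    def test_constant_unit_hazard(self):
        spec = HazardSpec("constant", ((0.0, 1.0),))
        assert cumulative_hazard(spec, 1.0) == pytest.approx(1.0, rel=1e-12)
        assert survival(spec, 1.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_dm_model_closed_form_values(self, dm_base_spec):
        # frozen from the quadrature oracle below
        assert cumulative_hazard(dm_base_spec, 1.0) == pytest.approx(
            0.27500488, abs=1e-7)
        assert cumulative_hazard(dm_base_spec, 7.37) == pytest.approx(
            0.47143386, abs=1e-7)
        assert survival(dm_base_spec, 1.0) == pytest.approx(0.75956841, abs=1e-7)

    def test_matches_quadrature_on_study_model(self, dm_base_spec):
        for t in (0.2, 0.5, 1.0, 3.0, 7.37):
            assert cumulative_hazard(dm_base_spec, t) == pytest.approx(
                quadrature_cumhaz(dm_base_spec, t), rel=1e-9)

    def test_survival_at_zero_is_one(self, dm_final_spec):
        assert survival(dm_final_spec, 0.0,
                        CovariateProfile({"IHD": 1, "HPLD": 1})) == 1.0

    def test_constant_halving(self):
        spec = HazardSpec("constant", ((0.0, math.log(2)),))
        assert survival(spec, 1.0) == pytest.approx(0.5, rel=1e-12)

    def test_weibull_divergent_shape_rejected(self):
        with pytest.raises(ValueError):
            HazardSpec("weibull", ((0.0, 1.0),), ((0.0, -1.2),))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.01, 10.0))
def test_closed_form_matches_quadrature(seed, t):
    """Property: exact piecewise integration equals adaptive quadrature."""
    spec = random_spec(np.random.default_rng(seed))
    h = cumulative_hazard(spec, t)
    q = quadrature_cumhaz(spec, t)
    assert h == pytest.approx(q, rel=1e-8, abs=1e-10)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.01, 5.0), st.floats(0.01, 5.0))
def test_cumhaz_additive_and_monotone(seed, t1, dt):
    """H(t) is non-decreasing and additive over contiguous intervals."""
    spec = random_spec(np.random.default_rng(seed))
    t2 = t1 + dt
    h1, h2 = cumulative_hazard(spec, t1), cumulative_hazard(spec, t2)
    assert h2 >= h1
    assert survival(spec, t2) <= survival(spec, t1) <= 1.0
    # H(0,t1) + H(t1,t2) == H(0,t2), with the middle term from quadrature
    middle = quadrature_cumhaz(spec, t2) - quadrature_cumhaz(spec, t1)
    assert h1 + middle == pytest.approx(h2, rel=1e-8, abs=1e-10)


@pytest.mark.parametrize("family", ["gompertz", "weibull"])
def test_zero_shape_degenerates_to_constant(family):
    spec = HazardSpec(family, ((0.0, 0.7), (2.0, 0.1)), ((0.0, 0.0), (3.0, 0.0)))
    const = HazardSpec("constant", ((0.0, 0.7), (2.0, 0.1)))
    for t in (0.1, 1.0, 2.5, 6.0):
        assert hazard_at(spec, t) == hazard_at(const, t)
        assert cumulative_hazard(spec, t) == pytest.approx(
            cumulative_hazard(const, t), rel=1e-14)


class TestSpecValidation:
    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            HazardSpec("constant", ((0.0, 0.0),))

    def test_first_segment_must_start_at_zero(self):
        with pytest.raises(ValueError):
            HazardSpec("constant", ((0.5, 1.0),))

    def test_segment_starts_strictly_increasing(self):
        with pytest.raises(ValueError):
            HazardSpec("constant", ((0.0, 1.0), (0.0, 2.0)))

    def test_constant_family_takes_no_shape(self):
        with pytest.raises(ValueError):
            HazardSpec("constant", ((0.0, 1.0),), ((0.0, 0.5),))


def test_serialization_roundtrip_bit_exact(dm_final_spec):
    """Saved and re-loaded models are numerically identical to the bit."""
    awkward = HazardSpec(
        "gompertz",
        ((0.0, 0.1 + 0.2), (0.5, 2.3e-3 / 7.0)),
        ((0.0, math.pi), (3.0, -1.0 / 3.0)),
        {"IHD": 0.1 + 1e-16, "HPLD": -0.835},
    )
    for spec in (dm_final_spec, awkward):
        back = HazardSpec.from_yaml(spec.to_yaml())
        assert back == spec
        assert all(a == b for a, b in zip(back.h0_segments, spec.h0_segments))


def test_serialization_file_roundtrip(tmp_path, dm_base_spec):
    path = tmp_path / "model.yaml"
    dm_base_spec.save(path)
    assert HazardSpec.load(path) == dm_base_spec
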