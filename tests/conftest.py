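import numpy as np
import pytest

from strokette import Censoring, CohortSpec, HazardSpec, generate_cohort, preset


@pytest.fixture(scope="session")
def dm_base_spec() -> HazardSpec:
    """Published covariate-free piecewise Gompertz hazard (diabetic cohort)."""
    return preset("dm_base").truth


@pytest.fixture(scope="session")
def dm_final_spec() -> HazardSpec:
    """Published final diabetic-cohort model (IHD and HPLD effects)."""
    return preset("dm_final").truth


@pytest.fixture(scope="session")
def gompertz_template() -> HazardSpec:
    """Free-parameter template matching the study's piecewise structure."""
    return HazardSpec("gompertz", ((0.0, 0.1), (0.5, 0.1)),
                      ((0.0, 0.0), (3.0, 0.0)))


@pytest.fixture(scope="session")
def constant_cohort():
    """2000 subjects from a constant hazard of 0.2/y, censored at 5 y."""
    spec = CohortSpec(
        n_subjects=2000,
        truth=HazardSpec("constant", ((0.0, 0.2),)),
        censoring=Censoring(5.0, None),
        seed=20240,
    )
    return generate_cohort(spec)


def quadrature_cumhaz(spec, t, profile=None, tol=1e-12):
    """Independent oracle: adaptive quadrature of the instantaneous hazard."""
    from scipy.integrate import quad

    from strokette import hazard_at

    if t == 0:
        return 0.0
    knots = [b for b in spec.breakpoints if 0 < b < t]
    edges = [0.0] + knots + [t]
    total = 0.0
    for a, b in zip(edges, edges[1:]):
        val, _ = quad(lambda s: hazard_at(spec, s, profile), a, b,
                      epsabs=tol, epsrel=tol, limit=500)
        total += val
    return total


def random_spec(rng: np.random.Generator) -> HazardSpec:
    """A random admissible hazard spec across all three families."""
    family = rng.choice(["constant", "gompertz", "weibull"])
    n_h0 = int(rng.integers(1, 4))
    h0_starts = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 8.0, n_h0 - 1))])
    h0 = tuple((float(a), float(rng.uniform(0.01, 2.0))) for a in h0_starts)
    if family == "constant":
        return HazardSpec("constant", h0)
    n_sh = int(rng.integers(1, 4))
    sh_starts = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 8.0, n_sh - 1))])
    lo, hi = (-0.5, 3.0) if family == "weibull" else (-2.0, 2.0)
    sh = tuple((float(a), float(rng.uniform(lo, hi))) for a in sh_starts)
    return HazardSpec(family, h0, sh)
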