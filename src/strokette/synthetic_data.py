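"""Synthetic registry-like stroke cohorts.

The registry data behind the recurrent-stroke analysis (a national
neurology registry, 2009–2016 development cohorts of 3493 diabetic and
4204 non-diabetic index-stroke patients, plus a 2017–2020 temporal
validation cohort of 1262 diabetic patients) is not publicly deposited.
This module generates cohorts with the statistical structure the
analysis assumes instead: binary baseline covariates drawn independently
with the published prevalences, administrative censoring at up to 7.37
years of follow-up (by default with a uniform accrual window, mimicking
staggered registration against a fixed cutoff), and event times drawn
from a piecewise Gompertz hazard with the published parameter estimates
as generative truth.

The presets are the study conditions, not tuning knobs: ``dm_final`` /
``nondm_final`` carry the published final-model parameters and
``dm_base`` / ``nondm_base`` the covariate-free baselines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .estimation import SubjectRecord
from .hazard_models import CovariateProfile, Family, HazardSpec
from .vpc import _simulate_times

__all__ = ["Censoring", "CohortSpec", "generate_cohort", "preset",
           "PRESET_NAMES", "covariate_prevalences"]

MAX_FOLLOWUP_YEARS = 7.37
#: default accrual window (years of follow-up): uniform between ~4.4 months
#: and the full 7.37 years, mimicking staggered enrolment with one cutoff
DEFAULT_ACCRUAL = (0.37, MAX_FOLLOWUP_YEARS)

# covariate prevalences among the development cohorts (recurrent and
# non-recurrent columns pooled): counts / cohort size
_DM_N = 3493
_NONDM_N = 4204
_PREVALENCES = {
    "dm": {
        "IHD": (52 + 420) / _DM_N,
        "HPLD": (96 + 1004) / _DM_N,
        "HTN": (180 + 2863) / _DM_N,
        "SMOKER": (113 + 1630) / _DM_N,
        "AF": (4 + 87) / _DM_N,
        "HU": (10 + 121) / _DM_N,
        "FHOS": (16 + 152) / _DM_N,
        "ANTIHLD": (167 + 2926) / _DM_N,
    },
    "nondm": {
        "IHD": (25 + 382) / _NONDM_N,
        "HPLD": (63 + 865) / _NONDM_N,
        "HTN": (108 + 2355) / _NONDM_N,
        "SMOKER": (89 + 1917) / _NONDM_N,
        "AF": (5 + 172) / _NONDM_N,
        "HU": (6 + 97) / _NONDM_N,
        "FHOS": (11 + 247) / _NONDM_N,
        "ANTIHLD": (120 + 3682) / _NONDM_N,
    },
}


def covariate_prevalences(group: str) -> dict[str, float]:
    """Published baseline-covariate prevalences for ``"dm"`` or ``"nondm"``.

    Includes covariates beyond the final models (smoking, atrial
    fibrillation, hyperuricemia, family history, lipid-lowering therapy)
    so simulation studies can carry realistic null decoys.
    """
    try:
        return dict(_PREVALENCES[group])
    except KeyError:
        raise ValueError(f"unknown group {group!r}; expected 'dm' or 'nondm'")


# published final-model hazards (piecewise Gompertz; baseline break at
# 0.5 y, shape break at 3 y)
_DM_BASE = HazardSpec(
    family=Family.GOMPERTZ,
    h0_segments=((0.0, 0.356), (0.5, 0.0023)),
    shape_segments=((0.0, 1.58), (3.0, 0.242)),
)
_NONDM_BASE = HazardSpec(
    family=Family.GOMPERTZ,
    h0_segments=((0.0, 0.253), (0.5, 0.0018)),
    shape_segments=((0.0, 1.7), (3.0, 0.213)),
)
_DM_FINAL = HazardSpec(
    family=_DM_BASE.family, h0_segments=_DM_BASE.h0_segments,
    shape_segments=_DM_BASE.shape_segments,
    covariate_coefficients={"IHD": 0.876, "HPLD": 0.633},
)
_NONDM_FINAL = HazardSpec(
    family=_NONDM_BASE.family, h0_segments=_NONDM_BASE.h0_segments,
    shape_segments=_NONDM_BASE.shape_segments,
    covariate_coefficients={"HPLD": 1.03, "HTN": 0.789, "ANTIHLD": -0.835},
)


@dataclass(frozen=True)
class Censoring:
    """Administrative censoring: fixed at ``max_years`` or uniform accrual."""

    max_years: float = MAX_FOLLOWUP_YEARS
    accrual_window: tuple[float, float] | None = DEFAULT_ACCRUAL

    def __post_init__(self) -> None:
        if self.max_years <= 0:
            raise ValueError("max_years must be > 0")
        if self.accrual_window is not None:
            lo, hi = self.accrual_window
            if not (0 < lo <= hi <= self.max_years):
                raise ValueError("accrual window must satisfy "
                                 "0 < min <= max <= max_years")


@dataclass(frozen=True)
class CohortSpec:
    """Generative truth for one synthetic cohort."""

    n_subjects: int
    truth: HazardSpec
    covariate_prevalences: Mapping[str, float] = field(default_factory=dict)
    censoring: Censoring = field(default_factory=Censoring)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name, p in self.covariate_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence of {name!r} must be in [0,1]")
        missing = set(self.truth.covariate_coefficients) - \
            set(self.covariate_prevalences)
        if missing:
            raise ValueError(f"truth uses covariate(s) {sorted(missing)} with "
                             "no generating prevalence")


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a cohort: covariates, censoring times, then event times.

    Covariates are independent Bernoulli draws; each subject's censoring
    time is either fixed at the maximum follow-up or uniform over the
    accrual window; the event time inverts the truth model's cumulative
    hazard.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    names = list(spec.covariate_prevalences)
    cov = {name: (rng.uniform(size=n) < spec.covariate_prevalences[name])
           .astype(int) for name in names}
    if spec.censoring.accrual_window is None:
        censor = np.full(n, spec.censoring.max_years)
    else:
        lo, hi = spec.censoring.accrual_window
        censor = rng.uniform(lo, hi, size=n)
    u = rng.uniform(size=n)

    truth_names = list(spec.truth.covariate_coefficients)
    coefs = np.asarray([spec.truth.covariate_coefficients[c]
                        for c in truth_names])
    lp = (np.column_stack([cov[c] for c in truth_names]) @ coefs
          if truth_names else np.zeros(n))
    t, ev = _simulate_times(spec.truth, lp, u, censor)

    return [
        SubjectRecord(
            id=i + 1, time=float(t[i]), event=int(ev[i]),
            covariates=CovariateProfile({c: int(cov[c][i]) for c in names}),
        )
        for i in range(n)
    ]


_PRESETS = {
    "dm_base": lambda: CohortSpec(
        n_subjects=_DM_N, truth=_DM_BASE, covariate_prevalences={}),
    "nondm_base": lambda: CohortSpec(
        n_subjects=_NONDM_N, truth=_NONDM_BASE, covariate_prevalences={}),
    "dm_final": lambda: CohortSpec(
        n_subjects=_DM_N, truth=_DM_FINAL,
        covariate_prevalences={k: _PREVALENCES["dm"][k]
                               for k in ("IHD", "HPLD", "HTN")}),
    "nondm_final": lambda: CohortSpec(
        n_subjects=_NONDM_N, truth=_NONDM_FINAL,
        covariate_prevalences={k: _PREVALENCES["nondm"][k]
                               for k in ("HPLD", "HTN", "ANTIHLD", "IHD")}),
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset(name: str) -> CohortSpec:
    """A fully populated :class:`CohortSpec` anchored to the published study.

    ``dm_final`` / ``nondm_final`` use the published final-model
    parameters as truth and the published covariate prevalences;
    ``dm_base`` / ``nondm_base`` are the covariate-free baselines.
    """
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
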