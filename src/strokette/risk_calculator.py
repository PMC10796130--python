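"""Recurrence-risk calculation for a patient profile.

Given a fitted hazard model and a patient's binary risk-factor profile,
the cumulative recurrence probability by time ``t`` is ``1 - S(t)``.
A conditional variant — the probability of a recurrence in a window
``(t1, t2]`` given none by ``t1`` — is also provided, since "risk after
t years" is ambiguous in clinical use and both readings are legitimate.
"""

from __future__ import annotations

from .hazard_models import CovariateProfile, HazardSpec, survival

__all__ = ["recurrence_probability", "conditional_recurrence_probability",
           "run_cli"]


def recurrence_probability(spec: HazardSpec,
                           profile: CovariateProfile | None,
                           t_years: float) -> float:
    """Cumulative probability of a recurrent stroke by ``t_years``.

    ``1 - S(t)``: non-decreasing in ``t`` and in any risk factor with a
    positive coefficient.
    """
    if t_years < 0:
        raise ValueError("t_years must be >= 0")
    return 1.0 - survival(spec, t_years, profile)


def conditional_recurrence_probability(spec: HazardSpec,
                                       profile: CovariateProfile | None,
                                       t1: float, t2: float) -> float:
    """P(recurrence in (t1, t2] | no recurrence by t1) = 1 - S(t2)/S(t1)."""
    if not (0 <= t1 <= t2):
        raise ValueError("need 0 <= t1 <= t2")
    s1 = survival(spec, t1, profile)
    s2 = survival(spec, t2, profile)
    return 1.0 - s2 / s1


def run_cli(argv) -> int:
    """Run the command-line interface; returns the process exit status."""
    from .cli import main

    try:
        main.main(args=list(argv), standalone_mode=True)
    except SystemExit as exc:
        code = exc.code
        return int(code) if code is not None else 0
    except Exception as exc:  # report, never traceback, for data errors
        import sys

        print(f"error: {exc}", file=sys.stderr)
        return 1
    return 0
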