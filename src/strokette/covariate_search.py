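"""Stepwise covariate modelling on a base hazard model.

Candidate binary covariates are screened univariately against the base
model, then selected by greedy forward inclusion (a covariate enters if
it drops the OFV by at least 3.84, i.e. p < 0.05 on 1 df, picking the
largest drop each round) followed by backward elimination (a covariate
is retained only if removing it would raise the OFV by at least 6.64,
i.e. p < 0.01 on 1 df).  Ties in the OFV drop are broken by covariate
name so runs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .estimation import (
    LRT_BACKWARD_RISE,
    LRT_FORWARD_DROP,
    FitResult,
    SubjectRecord,
    fit,
    lrt,
)
from .hazard_models import HazardSpec

__all__ = ["ScmStep", "ScmTrace", "univariate_screen", "stepwise"]


@dataclass(frozen=True)
class ScmStep:
    covariate: str
    direction: str            # "forward" | "backward"
    delta_ofv: float
    p_value: float
    decision: str             # "included" | "removed" | "retained" | "rejected"


@dataclass(frozen=True)
class ScmTrace:
    steps: tuple[ScmStep, ...]

    def as_tsv(self) -> str:
        lines = ["covariate\tdirection\tdelta_ofv\tp_value\tdecision"]
        for s in self.steps:
            lines.append(f"{s.covariate}\t{s.direction}\t{s.delta_ofv:.4f}"
                         f"\t{s.p_value:.4g}\t{s.decision}")
        return "\n".join(lines) + "\n"


def _with_candidate(spec: HazardSpec, name: str,
                    coefficient: float = 0.0) -> HazardSpec:
    coefs = dict(spec.covariate_coefficients)
    coefs[name] = coefficient
    return replace(spec, covariate_coefficients=coefs)


def _without(spec: HazardSpec, name: str) -> HazardSpec:
    coefs = {k: v for k, v in spec.covariate_coefficients.items() if k != name}
    return replace(spec, covariate_coefficients=coefs)


def _is_constant(data: Sequence[SubjectRecord], name: str) -> bool:
    vals = {s.covariates.values[name] for s in data}
    return len(vals) <= 1


def univariate_screen(data: Sequence[SubjectRecord], base: HazardSpec,
                      candidates: Sequence[str],
                      *, base_fit: FitResult | None = None,
                      ) -> dict[str, tuple[float, float]]:
    """OFV drop and LRT p-value for each candidate added alone to ``base``.

    A candidate column that is constant in the data carries no
    information; it is reported with a drop of 0 and p = 1.
    """
    if not candidates:
        return {}
    if base_fit is None:
        base_fit = fit(data, base)
    out: dict[str, tuple[float, float]] = {}
    for name in candidates:
        if _is_constant(data, name):
            out[name] = (0.0, 1.0)
            continue
        cand_fit = fit(data, _with_candidate(base_fit.spec, name),
                       start="template")
        drop = max(base_fit.ofv - cand_fit.ofv, 0.0)
        out[name] = (drop, lrt(base_fit.ofv, base_fit.ofv - drop, df=1))
    return out


def stepwise(data: Sequence[SubjectRecord], base: HazardSpec,
             candidates: Sequence[str], *,
             forward_threshold: float = LRT_FORWARD_DROP,
             backward_threshold: float = LRT_BACKWARD_RISE,
             ) -> tuple[FitResult, ScmTrace]:
    """Greedy forward inclusion then backward elimination.

    Returns the final fit and a trace recording every tested candidate
    with its OFV change, p-value, and decision.
    """
    steps: list[ScmStep] = []
    current = fit(data, base)
    remaining = sorted(candidates)

    # forward: add the candidate with the largest significant OFV drop
    while remaining:
        trial: dict[str, tuple[float, FitResult]] = {}
        for name in remaining:
            if _is_constant(data, name):
                trial[name] = (0.0, current)
                continue
            f = fit(data, _with_candidate(current.spec, name), start="template")
            trial[name] = (max(current.ofv - f.ofv, 0.0), f)
        # deterministic winner: largest drop, then lexicographic name
        winner = min(trial, key=lambda n: (-trial[n][0], n))
        win_drop = trial[winner][0]
        for name in sorted(trial):
            drop, _ = trial[name]
            p = lrt(current.ofv, current.ofv - drop, df=1)
            if name == winner and win_drop >= forward_threshold:
                decision = "included"
            else:
                decision = "rejected"
            steps.append(ScmStep(name, "forward", drop, p, decision))
        if win_drop < forward_threshold:
            break
        current = trial[winner][1]
        remaining.remove(winner)

    # backward: drop, one at a time, the covariate whose removal costs least,
    # until every remaining one costs at least the retention threshold
    included = sorted(set(current.spec.covariate_coefficients) -
                      set(base.covariate_coefficients))
    while included:
        rises: dict[str, tuple[float, FitResult]] = {}
        for name in included:
            f = fit(data, _without(current.spec, name), start="template")
            rises[name] = (max(f.ofv - current.ofv, 0.0), f)
        loser = min(rises, key=lambda n: (rises[n][0], n))
        rise = rises[loser][0]
        if rise >= backward_threshold:
            for name in sorted(rises):
                r, _ = rises[name]
                steps.append(ScmStep(name, "backward", r,
                                     lrt(current.ofv + r, current.ofv, df=1),
                                     "retained"))
            break
        steps.append(ScmStep(loser, "backward", rise,
                             lrt(current.ofv + rise, current.ofv, df=1),
                             "removed"))
        current = rises[loser][1]
        included.remove(loser)

    return current, ScmTrace(tuple(steps))
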