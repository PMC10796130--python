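"""Dataset CSV reading/writing and fit reports.

Dataset schema: a header row ``ID,TIME,EVENT`` followed by one column per
binary covariate; TIME is follow-up in decimal years (> 0), EVENT is 0/1.
The reader validates every row and reports all offending rows at once.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .estimation import FitResult, SirResult, SubjectRecord
from .hazard_models import CovariateProfile

REQUIRED_COLUMNS = ("ID", "TIME", "EVENT")


class DatasetError(ValueError):
    """Raised when a dataset file violates the schema; lists bad rows."""


def subjects_to_frame(data: Sequence[SubjectRecord]) -> pd.DataFrame:
    names = sorted({n for s in data for n in s.covariates.values})
    rows = []
    for s in data:
        row = {"ID": s.id, "TIME": s.time, "EVENT": s.event}
        row.update({n: s.covariates.values.get(n, 0) for n in names})
        rows.append(row)
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + names)


def frame_to_subjects(df: pd.DataFrame, *,
                      max_time: float | None = None) -> list[SubjectRecord]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetError(f"missing required column(s): {missing}")
    cov_names = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    problems: list[str] = []
    subjects: list[SubjectRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        r = row._asdict()
        label = f"row {i + 2}"  # 1-based plus header
        try:
            t = float(r["TIME"])
            ev = int(r["EVENT"])
        except (TypeError, ValueError) as exc:
            problems.append(f"{label}: unparseable TIME/EVENT ({exc})")
            continue
        if not np.isfinite(t) or t <= 0:
            problems.append(f"{label} (ID={r['ID']}): TIME must be > 0, got {r['TIME']}")
            continue
        if max_time is not None and t > max_time:
            problems.append(f"{label} (ID={r['ID']}): TIME {t} exceeds maximum "
                            f"follow-up {max_time}")
            continue
        if ev not in (0, 1):
            problems.append(f"{label} (ID={r['ID']}): EVENT must be 0/1, got {r['EVENT']}")
            continue
        cov = {}
        bad = False
        for name in cov_names:
            v = r[name]
            if v not in (0, 1, 0.0, 1.0):
                problems.append(f"{label} (ID={r['ID']}): covariate {name}={v!r} "
                                "is not 0/1")
                bad = True
                break
            cov[name] = int(v)
        if bad:
            continue
        subjects.append(SubjectRecord(id=r["ID"], time=t, event=ev,
                                      covariates=CovariateProfile(cov)))
    if problems:
        raise DatasetError("dataset validation failed:\n  " + "\n  ".join(problems))
    ids = [s.id for s in subjects]
    if len(set(ids)) != len(ids):
        raise DatasetError("duplicate subject IDs (one row per subject required)")
    return subjects


def read_subjects(path, *, max_time: float | None = None) -> list[SubjectRecord]:
    """Read a dataset CSV, validating schema and every row."""
    df = pd.read_csv(path)
    return frame_to_subjects(df, max_time=max_time)


def write_subjects(data: Sequence[SubjectRecord], path) -> None:
    subjects_to_frame(data).to_csv(path, index=False)


def fit_report(result: FitResult, sir: SirResult | None = None) -> str:
    """Human-readable summary of a fit (plus SIR uncertainty if given)."""
    res = result if sir is None else result.with_uncertainty(sir)
    lines = [
        f"family       : {res.spec.family.value}",
        f"subjects     : {res.n_subjects} ({res.n_events} events)",
        f"OFV (-2logL) : {res.ofv:.4f}",
        f"converged    : {res.converged}" + (f"  [{res.message}]" if res.message else ""),
        "",
        f"{'parameter':<14}{'estimate':>12}{'RSE%':>9}{'95% CI':>22}",
    ]
    for name, est in res.estimates.items():
        rse = f"{res.rse_percent[name]:.2f}" if res.rse_percent else "-"
        if res.ci and name in res.ci:
            lo, hi = res.ci[name]
            ci = f"({lo:.4g}, {hi:.4g})"
        else:
            ci = "-"
        lines.append(f"{name:<14}{est:>12.5g}{rse:>9}{ci:>22}")
    hr = res.hr_table
    if hr:
        lines += ["", f"{'covariate':<14}{'HR':>8}{'95% CI':>20}"]
        for cov, (h, lo, hi) in hr.items():
            lines.append(f"{cov:<14}{h:>8.3f}   ({lo:.3f}, {hi:.3f})")
    return "\n".join(lines) + "\n"
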