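"""Cohort bookkeeping: run-to-patient collapsing, recurrence, burden, matrices.

The study design this mirrors has two cohorts of patients: cases may
contribute several RNA-seq runs each (e.g. three per patient), controls
one run each.  The unit of analysis is the distinct patient — a patient
is positive for a fusion transcript if any one of its runs contains it —
so recurrence counts are always patient counts, never run counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

CASE = "case"
CONTROL = "control"
COHORTS = (CASE, CONTROL)

#: Patient-recurrence threshold: a fusion enters testing only when at
#: least this many distinct patients of a cohort carry it (n*p >= 5).
DEFAULT_MIN_COUNT = 5


class DesignError(ValueError):
    """Raised for malformed cohort designs or design/call mismatches."""


@dataclass
class CohortDesign:
    """Run-to-patient mapping plus the case/control split.

    ``n_case`` and ``n_control`` are distinct patient counts; every run
    maps to exactly one patient, and every patient to exactly one
    cohort.
    """

    run_to_patient: dict[str, str]
    patient_to_cohort: dict[str, str]

    def __post_init__(self) -> None:
        bad = sorted({c for c in self.patient_to_cohort.values() if c not in COHORTS})
        if bad:
            raise DesignError(f"unknown cohort labels: {bad}; expected {list(COHORTS)}")
        orphans = sorted(
            {p for p in self.run_to_patient.values() if p not in self.patient_to_cohort}
        )
        if orphans:
            raise DesignError(f"runs map to patients without a cohort: {orphans}")

    @property
    def n_case(self) -> int:
        return sum(1 for c in self.patient_to_cohort.values() if c == CASE)

    @property
    def n_control(self) -> int:
        return sum(1 for c in self.patient_to_cohort.values() if c == CONTROL)

    def cohort_size(self, cohort: str) -> int:
        if cohort == CASE:
            return self.n_case
        if cohort == CONTROL:
            return self.n_control
        raise DesignError(f"unknown cohort {cohort!r}; expected one of {list(COHORTS)}")

    def patients(self, cohort: Optional[str] = None) -> list[str]:
        """Patient IDs, sorted; optionally restricted to one cohort."""
        if cohort is not None and cohort not in COHORTS:
            raise DesignError(f"unknown cohort {cohort!r}; expected one of {list(COHORTS)}")
        return sorted(
            p
            for p, c in self.patient_to_cohort.items()
            if cohort is None or c == cohort
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortDesign":
        """Build from a table with columns run_id, patient_id, cohort."""
        required = {"run_id", "patient_id", "cohort"}
        missing = required - set(df.columns)
        if missing:
            raise DesignError(f"design table missing columns: {sorted(missing)}")
        run_to_patient: dict[str, str] = {}
        patient_to_cohort: dict[str, str] = {}
        for row in df.itertuples(index=False):
            run, patient, cohort = str(row.run_id), str(row.patient_id), str(row.cohort)
            if run in run_to_patient and run_to_patient[run] != patient:
                raise DesignError(f"run {run!r} mapped to multiple patients")
            run_to_patient[run] = patient
            if patient in patient_to_cohort and patient_to_cohort[patient] != cohort:
                raise DesignError(f"patient {patient!r} assigned to multiple cohorts")
            patient_to_cohort[patient] = cohort
        return cls(run_to_patient, patient_to_cohort)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"run_id": r, "patient_id": p, "cohort": self.patient_to_cohort[p]}
            for r, p in sorted(self.run_to_patient.items())
        ]
        return pd.DataFrame(rows, columns=["run_id", "patient_id", "cohort"])


Presence = dict[str, set[str]]
"""Per-patient presence: patient ID -> set of fusion transcript IDs."""


def collapse_runs_to_patients(calls: pd.DataFrame, design: CohortDesign) -> Presence:
    """Collapse per-run fusion calls to per-patient presence sets.

    A patient is positive for a fusion iff at least one of its runs
    contains a call for it, so the operation is idempotent under
    duplicated run records.  Every patient in the design appears in the
    result, possibly with an empty set.

    Raises
    ------
    DesignError
        If any run ID in ``calls`` is absent from the design (all
        offenders are listed).
    """
    for col in ("run_id", "fusion_id"):
        if col not in calls.columns:
            raise DesignError(f"calls table missing column {col!r}")
    presence: Presence = {p: set() for p in design.patient_to_cohort}
    unknown = sorted(set(calls["run_id"].astype(str)) - set(design.run_to_patient))
    if unknown:
        raise DesignError(f"calls reference run IDs absent from design: {unknown}")
    for run, fusion in zip(calls["run_id"].astype(str), calls["fusion_id"].astype(str)):
        presence[design.run_to_patient[run]].add(fusion)
    return presence


def recurrence_table(
    presence: Presence,
    design: CohortDesign,
    fusion_ids: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-(fusion, cohort) patient counts and exact frequencies.

    The fusion universe defaults to everything observed in any patient;
    fusions absent from a cohort get count 0 there.  Frequencies are
    exact ``positive_patients / cohort_size`` and are never rounded
    here.
    """
    if fusion_ids is None:
        universe = sorted(set().union(*presence.values()) if presence else set())
    else:
        universe = sorted(set(map(str, fusion_ids)))
    counts = {(f, c): 0 for f in universe for c in COHORTS}
    for patient, fusions in presence.items():
        cohort = design.patient_to_cohort.get(patient)
        if cohort is None:
            raise DesignError(f"presence includes patient {patient!r} absent from design")
        for f in fusions:
            if f in set(universe):
                counts[(f, cohort)] += 1
    sizes = {CASE: design.n_case, CONTROL: design.n_control}
    rows = [
        {
            "fusion_id": f,
            "cohort": c,
            "positive_patients": counts[(f, c)],
            "cohort_size": sizes[c],
            "frequency": counts[(f, c)] / sizes[c] if sizes[c] else np.nan,
        }
        for f in universe
        for c in COHORTS
    ]
    return pd.DataFrame(
        rows,
        columns=["fusion_id", "cohort", "positive_patients", "cohort_size", "frequency"],
    )


def filter_recurrent(
    records: pd.DataFrame, cohort: str, min_count: int = DEFAULT_MIN_COUNT
) -> list[str]:
    """Fusions with >= min_count positive patients in the named cohort.

    The boundary is inclusive (exactly min_count is retained).  Output
    order is deterministic: descending patient count, then fusion_id.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    if cohort not in COHORTS:
        raise DesignError(f"unknown cohort {cohort!r}; expected one of {list(COHORTS)}")
    sub = records[records["cohort"] == cohort]
    sub = sub[sub["positive_patients"] >= min_count]
    sub = sub.sort_values(
        ["positive_patients", "fusion_id"], ascending=[False, True], kind="mergesort"
    )
    return sub["fusion_id"].tolist()


def burden_per_sample(
    presence: Presence,
    design: CohortDesign,
    cohort: Optional[str] = None,
    class_of: Optional[Mapping[str, str]] = None,
    class_filter: Optional[str] = None,
) -> tuple[pd.Series, tuple[int, int, float]]:
    """Distinct positive fusion transcripts per patient, with summary.

    ``class_of`` maps fusion_id -> category and, with ``class_filter``
    (e.g. "EFG" or "GENOMIC"), restricts the burden to one class.
    Returns ``(per-patient counts as a Series indexed by patient ID,
    (min, max, mean))``; min/max/mean over an empty cohort are
    ``(0, 0, nan)``.
    """
    if class_filter is not None and class_of is None:
        raise ValueError("class_filter requires class_of")
    patients = design.patients(cohort)
    counts = {}
    for p in patients:
        fusions = presence.get(p, set())
        if class_filter is not None:
            fusions = {f for f in fusions if class_of.get(f) == class_filter}
        counts[p] = len(fusions)
    series = pd.Series(counts, name="burden", dtype=int)
    if len(series):
        summary = (int(series.min()), int(series.max()), float(series.mean()))
    else:
        summary = (0, 0, float("nan"))
    return series, summary


def presence_matrix(
    presence: Presence,
    design: CohortDesign,
    fusion_ids: Iterable[str],
    cohort: Optional[str] = None,
) -> pd.DataFrame:
    """Binary patients x fusion-transcripts matrix for heatmap export.

    Rows are patients sorted by ID (optionally one cohort); columns are
    the given fusions ordered by descending case patient count then
    fusion_id, so the most case-recurrent fusions come first.  Entry is
    1 iff the patient is positive; column sums therefore reproduce the
    recurrence counts.
    """
    fusion_ids = [str(f) for f in fusion_ids]
    patients = design.patients(cohort)
    case_counts = {f: 0 for f in fusion_ids}
    for p in design.patients(CASE):
        for f in presence.get(p, set()):
            if f in case_counts:
                case_counts[f] += 1
    columns = sorted(fusion_ids, key=lambda f: (-case_counts[f], f))
    data = np.zeros((len(patients), len(columns)), dtype=int)
    col_idx = {f: i for i, f in enumerate(columns)}
    for i, p in enumerate(patients):
        for f in presence.get(p, set()):
            j = col_idx.get(f)
            if j is not None:
                data[i, j] = 1
    return pd.DataFrame(data, index=patients, columns=columns)
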