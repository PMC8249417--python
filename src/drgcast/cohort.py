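"""Cohort eligibility filters and patient-level train/test and CV splitting.

Eligibility follows the early-prediction study design: adult patients
(age strictly over 18 by default), stays with a single ICU visit, and at
least one clinical note charted within 48 hours of ICU admission.  All
splits are made at the patient level so no patient contributes stays to
both sides of any split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthgen import DrgCatalog, StayRecord


class EmptyCohortError(ValueError):
    """Raised when no stay survives the eligibility filters."""


class SplitError(ValueError):
    """Raised when a split plan cannot be constructed."""


@dataclass(frozen=True)
class CohortDataset:
    """Eligible stays plus the model's full label space.

    ``label_space`` covers the whole (exclusion-filtered) catalog for the
    system, not merely the codes observed among the stays, so a model can
    score codes it never saw in training.
    """

    stays: tuple[StayRecord, ...]
    system: str
    label_space: tuple[str, ...]


@dataclass(frozen=True)
class SplitPlan:
    test_patient_ids: frozenset[str]
    cv_folds: tuple[frozenset[str], ...]
    seed: int


def _eligible(stay: StayRecord, codes: set[str], min_age: int, inclusive: bool,
              window_hpa: float) -> bool:
    age_ok = stay.age >= min_age if inclusive else stay.age > min_age
    return (age_ok
            and stay.n_icu_visits == 1
            and any(n.chart_hpa <= window_hpa for n in stay.notes)
            and stay.drg_code in codes)


def build_cohort(stays, catalog: DrgCatalog, system: str | None = None, *,
                 min_age: int = 18, inclusive_age: bool = False,
                 window_hpa: float = 48.0) -> CohortDataset:
    """Apply the eligibility filters and fix the label space.

    Retains exactly the stays with age > ``min_age`` (>= with
    ``inclusive_age``), a single ICU visit, at least one note with
    chart time <= ``window_hpa``, and a DRG code present in the catalog.
    """
    if system is None:
        if not catalog.entries:
            raise EmptyCohortError("empty catalog")
        system = catalog.entries[0].system
    codes = set(catalog.codes(system))
    kept = tuple(s for s in stays
                 if s.drg_system == system
                 and _eligible(s, codes, min_age, inclusive_age, window_hpa))
    if not kept:
        raise EmptyCohortError(f"no eligible stay for system {system}")
    return CohortDataset(stays=kept, system=system, label_space=tuple(sorted(codes)))


def split_train_test(cohort: CohortDataset, test_frac: float = 0.10,
                     seed: int = 0) -> SplitPlan:
    """Hold out whole patients until the test side holds >= ``test_frac`` of stays.

    Patients are taken in a seeded shuffled order, so the test stay share
    overshoots the target by at most one patient's stays.
    """
    if not 0.0 < test_frac < 1.0:
        raise SplitError(f"test_frac must lie in (0, 1), got {test_frac}")
    stays_per_patient: dict[str, int] = {}
    for s in cohort.stays:
        stays_per_patient[s.patient_id] = stays_per_patient.get(s.patient_id, 0) + 1
    patients = sorted(stays_per_patient)
    if len(patients) < 2:
        raise SplitError("cannot split a cohort with a single patient")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    target = test_frac * len(cohort.stays)
    test: set[str] = set()
    n_test_stays = 0
    for i in order:
        if n_test_stays >= target:
            break
        pid = patients[i]
        test.add(pid)
        n_test_stays += stays_per_patient[pid]
    if len(test) == len(patients):
        raise SplitError("test fraction leaves no training patient")
    return SplitPlan(test_patient_ids=frozenset(test), cv_folds=(), seed=seed)


def make_cv_folds(train_patients, k: int = 5, seed: int = 0) -> tuple[frozenset[str], ...]:
    """Partition patients into k near-equal disjoint folds (seeded shuffle)."""
    if k < 2:
        raise SplitError(f"need k >= 2 folds, got {k}")
    patients = sorted(train_patients)
    if len(patients) < k:
        raise SplitError(f"need at least {k} patients, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    folds = np.array_split(order, k)
    return tuple(frozenset(patients[i] for i in f) for f in folds)


def make_test_population(cohort: CohortDataset, split: SplitPlan) -> list[StayRecord]:
    """One stay per test patient: the earliest admission (the 'patient group').

    Used for population-level cost estimation, where each patient should
    contribute a single hospital visit.
    """
    first: dict[str, StayRecord] = {}
    for s in cohort.stays:
        if s.patient_id not in split.test_patient_ids:
            continue
        cur = first.get(s.patient_id)
        if cur is None or (s.admission_index, s.stay_id) < (cur.admission_index, cur.stay_id):
            first[s.patient_id] = s
    return [first[pid] for pid in sorted(first)]
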