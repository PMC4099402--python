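"""Shared builders and independent brute-force oracles for the test suite."""

from __future__ import annotations

import datetime as dt
from itertools import combinations

import pytest
from hypothesis import settings

from herbnet.cohort import Cohort
from herbnet.model import ClaimsDataset, PrescriptionItem, VisitRecord

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

A_DATE = dt.date(2005, 6, 1)


def make_item(chm_id: str, chm_type: str = "SH", dose: float = 1.3,
              duration: int = 7, admin: int = 3) -> PrescriptionItem:
    return PrescriptionItem(chm_id, f"name of {chm_id}", chm_type, dose, duration, admin)


def make_visit(visit_id: str, items: list[PrescriptionItem] | None = None,
               diagnoses: tuple[str, ...] = ("625.4",),
               modality: frozenset[str] | None = None,
               patient_id: str = "P1", date: dt.date = A_DATE) -> VisitRecord:
    items = items or []
    if modality is None:
        modality = frozenset({"CHM"}) if items else frozenset({"ACUPUNCTURE"})
    return VisitRecord(visit_id, patient_id, date, diagnoses, modality, tuple(items))


def cohort_of(item_sets: list[list[str]], types: dict[str, str] | None = None) -> Cohort:
    """A cohort whose prescriptions are the given chm_id lists."""
    types = types or {}
    visits = [
        make_visit(f"V{i}", [make_item(c, types.get(c, "SH")) for c in ids],
                   patient_id=f"P{i}")
        for i, ids in enumerate(item_sets)
    ]
    return Cohort(visits=visits, n_all_target_visits=len(visits),
                  n_chm_prescriptions=len(visits), n_patients=len(visits))


def dataset_of(visits: list[VisitRecord]) -> ClaimsDataset:
    return ClaimsDataset.from_visits(visits)


# ---------------------------------------------------------------- oracles

def brute_force_itemsets(item_sets: list[frozenset[str]], min_support: float,
                         max_size: int) -> dict[frozenset[str], int]:
    """Enumerate every itemset up to max_size and count by direct subset scan.

    Independent of the Apriori implementation: no pruning, no candidate
    generation — the definitionally-correct answer for small instances.
    """
    n = len(item_sets)
    universe = sorted(set().union(*item_sets)) if item_sets else []
    out: dict[frozenset[str], int] = {}
    for k in range(1, max_size + 1):
        for combo in combinations(universe, k):
            s = frozenset(combo)
            count = sum(1 for t in item_sets if s <= t)
            if count >= min_support * n:
                out[s] = count
    return out


def brute_force_item_counts(item_sets: list[frozenset[str]]) -> dict[str, int]:
    universe = set().union(*item_sets) if item_sets else set()
    return {c: sum(1 for t in item_sets if c in t) for c in universe}


def brute_force_pair_counts(item_sets: list[frozenset[str]]) -> dict[frozenset[str], int]:
    universe = sorted(set().union(*item_sets)) if item_sets else []
    out = {}
    for a, b in combinations(universe, 2):
        c = sum(1 for t in item_sets if a in t and b in t)
        if c:
            out[frozenset({a, b})] = c
    return out


@pytest.fixture(scope="session")
def small_synthetic():
    """One shared small synthetic dataset (plus truth and cohort)."""
    from herbnet.cohort import select_cohort
    from herbnet.simulate import default_pms_config, generate_claims

    cfg = default_pms_config(seed=11, n_patients=1200)
    data, truth = generate_claims(cfg)
    return data, truth, select_cohort(data)
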