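"""Cohort selection: PMS-only CHM prescriptions from a claims dataset.

The inclusion/exclusion procedure mirrors how claims studies of herbal
prescribing isolate a clean indication: keep ambulatory visits whose
diagnosis list is exactly the target ICD-9 code (sole-diagnosis rule, which
removes co-morbidity-driven prescriptions), then drop visits where
acupuncture or massage accompanied the prescription (those modalities can
shift CHM choice). Two denominators are tracked because descriptive tables
downstream are denominated by CHM prescriptions while the modality share is
denominated by all target-diagnosis visits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import ACUPUNCTURE, CHM, MASSAGE, ClaimsDataset, VisitRecord, normalize_icd9, round_half_up

__all__ = ["CohortConfig", "Cohort", "select_cohort", "cohort_summary"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortConfig:
    """Inclusion/exclusion rules; defaults reproduce the PMS study design."""

    target_code: str = "625.4"
    require_sole_diagnosis: bool = True
    exclude_modalities: frozenset[str] = frozenset({ACUPUNCTURE, MASSAGE})
    require_chm: bool = True

    def __post_init__(self) -> None:
        if not self.target_code.strip():
            raise ValueError("target_code must be non-empty")


@dataclass
class Cohort:
    """The analysis cohort plus its two audit denominators.

    ``n_all_target_visits`` counts visits passing the diagnosis rules before
    modality filtering; ``n_chm_prescriptions`` (N) is the final denominator
    for every prevalence table.
    """

    visits: list[VisitRecord]
    n_all_target_visits: int
    n_chm_prescriptions: int
    n_patients: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_chm_prescriptions > self.n_all_target_visits:
            raise ValueError("n_chm_prescriptions cannot exceed n_all_target_visits")
        # counts-only cohorts (no visit records, e.g. published totals) are allowed
        if self.visits and len(self.visits) != self.n_chm_prescriptions:
            raise ValueError("n_chm_prescriptions inconsistent with retained visit list")


def _diagnosis_match(visit: VisitRecord, config: CohortConfig) -> bool:
    target = normalize_icd9(config.target_code)
    if config.require_sole_diagnosis:
        return visit.diagnoses == (target,)
    return bool(visit.diagnoses) and visit.diagnoses[0] == target


def select_cohort(data: ClaimsDataset, config: CohortConfig | None = None) -> Cohort:
    """Apply the diagnosis and modality rules; an empty cohort is valid.

    A visit enters ``n_all_target_visits`` iff its diagnosis list satisfies
    the target rule; it is retained iff additionally it is a CHM visit with a
    nonempty prescription and carries none of the excluded modalities.
    """
    config = config or CohortConfig()
    retained: list[VisitRecord] = []
    n_target = 0
    n_empty_chm = 0
    for v in data.visits:
        if not _diagnosis_match(v, config):
            continue
        n_target += 1
        if v.modality & config.exclude_modalities:
            continue
        if config.require_chm:
            if CHM not in v.modality:
                continue
            if not v.items:
                n_empty_chm += 1
                continue
        retained.append(v)
    if n_empty_chm:
        logger.info("excluded %d CHM visits with empty prescriptions", n_empty_chm)
    patients = {v.patient_id for v in retained}
    return Cohort(
        visits=retained,
        n_all_target_visits=n_target,
        n_chm_prescriptions=len(retained),
        n_patients=len(patients),
    )


def cohort_summary(cohort: Cohort) -> dict:
    """Headline counts plus the CHM share of target visits (one decimal %).

    With zero target visits the share is ``None`` (undefined), never 0.
    """
    if cohort.n_all_target_visits:
        share = round_half_up(
            100.0 * cohort.n_chm_prescriptions / cohort.n_all_target_visits, 1
        )
    else:
        share = None
    return {
        "n_patients": cohort.n_patients,
        "n_all_target_visits": cohort.n_all_target_visits,
        "n_chm_prescriptions": cohort.n_chm_prescriptions,
        "chm_share_pct": share,
    }
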