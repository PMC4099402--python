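"""Descriptive prescription statistics: prevalence tables and dosing summaries.

Prevalence here is the fraction of cohort prescriptions containing a CHM (or
an unordered CHM pair), reported as a percent of N = the number of CHM
prescriptions. "Instances" counts prescriptions, not grams and not patients.
Mean dose and duration are averaged over the prescriptions that contain the
CHM — the only denominator available per product.
"""

from __future__ import annotations

import logging
from collections import Counter
from itertools import combinations
from statistics import mean

from .cohort import Cohort
from .model import round_half_up

__all__ = [
    "make_item_row",
    "make_pair_row",
    "item_prevalence",
    "pair_prevalence",
    "combo_type_share",
    "prescription_size_stats",
    "dosing_frequency_distribution",
    "EmptyCohortError",
]

logger = logging.getLogger(__name__)

ITEM_COLUMNS = ["chm_id", "chm_type", "instances", "dose_g_per_day", "duration_days", "prevalence_pct"]
PAIR_COLUMNS = ["chm_a", "chm_b", "instances", "prevalence_pct"]


class EmptyCohortError(ValueError):
    """Raised when a prevalence denominator would be zero."""


def make_item_row(
    chm_id: str,
    chm_type: str,
    instances: int,
    dose: float | None,
    duration: float | None,
    n: int,
) -> dict:
    """Assemble one prevalence-table row, computing the percent from counts."""
    return {
        "chm_id": chm_id,
        "chm_type": chm_type,
        "instances": instances,
        "dose_g_per_day": dose,
        "duration_days": duration,
        "prevalence_pct": round_half_up(100.0 * instances / n, 1),
    }


def make_pair_row(chm_a: str, chm_b: str, instances: int, n: int) -> dict:
    if chm_a == chm_b:
        raise ValueError(f"pair members must differ, got {chm_a!r} twice")
    return {
        "chm_a": chm_a,
        "chm_b": chm_b,
        "instances": instances,
        "prevalence_pct": round_half_up(100.0 * instances / n, 1),
    }


def _require_nonempty(cohort: Cohort) -> int:
    n = cohort.n_chm_prescriptions
    if n == 0:
        raise EmptyCohortError(
            "prevalence undefined: cohort has zero CHM prescriptions (N = 0)"
        )
    return n


def item_prevalence(cohort: Cohort) -> list[dict]:
    """One row per distinct CHM in the cohort, sorted by instances descending.

    Ties break lexicographically on chm_id so output order is deterministic.
    """
    n = _require_nonempty(cohort)
    counts: Counter[str] = Counter()
    doses: dict[str, list[float]] = {}
    durations: dict[str, list[int]] = {}
    types: dict[str, str] = {}
    for v in cohort.visits:
        for it in v.items:
            counts[it.chm_id] += 1
            doses.setdefault(it.chm_id, []).append(it.dose_g_per_day)
            durations.setdefault(it.chm_id, []).append(it.duration_days)
            types[it.chm_id] = it.chm_type
    rows = [
        make_item_row(cid, types[cid], c, mean(doses[cid]), mean(durations[cid]), n)
        for cid, c in counts.items()
    ]
    rows.sort(key=lambda r: (-r["instances"], r["chm_id"]))
    return rows


def pair_prevalence(cohort: Cohort) -> list[dict]:
    """One row per unordered CHM pair co-occurring in >= 1 prescription.

    Pair members are ordered within the row by descending single-item
    instances then lexicographically; rows sort by pair instances descending
    with the same canonical order as tie-break.
    """
    n = _require_nonempty(cohort)
    single: Counter[str] = Counter()
    pairs: Counter[tuple[str, str]] = Counter()
    for v in cohort.visits:
        ids = sorted(v.item_set)
        single.update(ids)
        pairs.update(combinations(ids, 2))
    rows = []
    for (a, b), c in pairs.items():
        if (single[b], a) > (single[a], b):  # descending instances, then lexicographic
            a, b = b, a
        rows.append(make_pair_row(a, b, c, n))
    rows.sort(key=lambda r: (-r["instances"], r["chm_a"], r["chm_b"]))
    return rows


def combo_type_share(
    pairs: list[dict], catalog: dict[str, str] | dict[str, tuple[str, str]]
) -> dict[str, float]:
    """Classify top-k pairs as HF-HF / HF-SH / SH-SH and return percents of k.

    ``catalog`` maps chm_id to its type, or to a (name, type) tuple as held
    on :class:`~herbnet.model.ClaimsDataset`.
    """
    if not pairs:
        raise ValueError("need at least one pair to classify")

    def type_of(cid: str) -> str:
        try:
            entry = catalog[cid]
        except KeyError:
            raise KeyError(f"chm_id {cid!r} missing from catalog") from None
        return entry if isinstance(entry, str) else entry[1]

    counts = {"HF-HF": 0, "HF-SH": 0, "SH-SH": 0}
    for row in pairs:
        kinds = sorted((type_of(row["chm_a"]), type_of(row["chm_b"])))
        counts["-".join(kinds)] += 1
    k = len(pairs)
    return {key: round_half_up(100.0 * c / k, 1) for key, c in counts.items()}


def prescription_size_stats(cohort: Cohort) -> dict:
    """Mean items per prescription (one decimal) plus the full size histogram."""
    _require_nonempty(cohort)
    sizes = [len(v.items) for v in cohort.visits]
    hist = dict(sorted(Counter(sizes).items()))
    return {
        "mean_items": round_half_up(mean(sizes), 1),
        "mean_items_exact": mean(sizes),
        "histogram": hist,
    }


def dosing_frequency_distribution(cohort: Cohort) -> dict[int, float]:
    """Percent of prescriptions by administrations per day.

    The frequency is a prescription-level attribute; if items within one
    prescription disagree the prescription is counted by its modal value
    (logged), lowest value winning a modal tie.
    """
    n = _require_nonempty(cohort)
    counts: Counter[int] = Counter()
    n_mixed = 0
    for v in cohort.visits:
        freqs = [it.admin_per_day for it in v.items]
        if len(set(freqs)) > 1:
            n_mixed += 1
        modal = max(sorted(set(freqs)), key=freqs.count)
        counts[modal] += 1
    if n_mixed:
        logger.info("resolved %d prescriptions with mixed admin_per_day by mode", n_mixed)
    return {k: round_half_up(100.0 * c / n, 1) for k, c in sorted(counts.items())}
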