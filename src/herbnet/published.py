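"""Published reference counts from the nationwide PMS claims analysis.

The source cohort (Taiwan NHI two-million-beneficiary sample, 1998-2011,
ambulatory visits with ICD-9 625.4 as the sole diagnosis) is not publicly
redistributable, but the study's printed summary tables are: the top herbal
formulas and single herbs with prescription counts, mean dose and duration,
and the ten most common two-CHM combinations, all denominated by
N = 13,820 CHM prescriptions. These constants let the pipeline's statistics
be exercised as worked examples — every printed prevalence percentage is
recomputed here from its printed numerator and denominator — and let the
co-prescription network be rebuilt from the printed top-10 pair list.
"""

from __future__ import annotations

__all__ = [
    "N_PATIENTS",
    "N_TARGET_VISITS",
    "N_CHM_PRESCRIPTIONS",
    "TOP_HF",
    "TOP_SH",
    "TOP_PAIRS",
    "item_rows",
    "pair_rows",
    "network_item_rows",
]

N_PATIENTS = 5_668
#: ambulatory TCM visits with PMS as the sole diagnosis
N_TARGET_VISITS = 14_312
#: the subset of those visits at which CHM was prescribed (the table denominator)
N_CHM_PRESCRIPTIONS = 13_820

JWXYS = "Jia-Wei-Xiao-Yao-San"
DGSYS = "Dang-Gui-Shao-Yao-San"
GZFLW = "Gui-Zhi-Fu-Ling-Wan"
CYPERUS = "Cyperus rotundus"
LEONURUS = "Leonurus heterophyllus"
CORYDALIS = "Corydalis yanhusuo"
SALVIA = "Salvia miltiorrhiza"
SCUTELLARIA = "Scutellaria baicalensis"
CURCUMA = "Curcuma longa"

#: top five herbal formulas: (name, instances, mean dose g/day, mean duration days)
TOP_HF: list[tuple[str, int, float, float]] = [
    (JWXYS, 5_185, 4.87, 6.4),
    (DGSYS, 2_064, 4.34, 6.4),
    (GZFLW, 1_245, 3.87, 6.3),
    ("Wen-Jing-Tang", 1_120, 4.25, 6.3),
    ("Shao-Fu-Zhu-Yu-Tang", 994, 3.97, 6.2),
]

#: top ten single herbs, same column layout
TOP_SH: list[tuple[str, int, float, float]] = [
    (CYPERUS, 2_485, 1.38, 6.3),
    (LEONURUS, 2_097, 1.33, 6.3),
    (CORYDALIS, 1_573, 1.28, 6.2),
    (SALVIA, 1_281, 1.30, 6.4),
    ("Eucommia ulmoides", 1_023, 1.26, 6.3),
    (SCUTELLARIA, 858, 1.30, 6.5),
    ("Dipsacus asperoides", 644, 1.17, 6.4),
    ("Cuscuta chinensis", 639, 1.44, 6.6),
    ("Pueraria lobata", 616, 1.33, 6.4),
    ("Paeonia suffruticosa", 605, 1.43, 6.6),
]

#: top ten two-CHM combinations: (chm_a, chm_b, instances)
TOP_PAIRS: list[tuple[str, str, int]] = [
    (JWXYS, CYPERUS, 1_059),
    (JWXYS, LEONURUS, 818),
    (CYPERUS, LEONURUS, 773),
    (JWXYS, CORYDALIS, 564),
    (CYPERUS, CORYDALIS, 512),
    (JWXYS, SALVIA, 467),
    (CYPERUS, SALVIA, 377),
    (JWXYS, GZFLW, 375),
    (JWXYS, SCUTELLARIA, 262),
    (JWXYS, CURCUMA, 251),
]


def item_rows() -> list[dict]:
    """Printed single-CHM tables as ``ItemPrevalenceRow``-shaped dicts."""
    from .stats import make_item_row

    rows = [
        make_item_row(name, "HF", inst, dose, dur, N_CHM_PRESCRIPTIONS)
        for name, inst, dose, dur in TOP_HF
    ] + [
        make_item_row(name, "SH", inst, dose, dur, N_CHM_PRESCRIPTIONS)
        for name, inst, dose, dur in TOP_SH
    ]
    return sorted(rows, key=lambda r: (-r["instances"], r["chm_id"]))


def pair_rows() -> list[dict]:
    """Printed pair table as ``PairPrevalenceRow``-shaped dicts."""
    from .stats import make_pair_row

    return [
        make_pair_row(a, b, inst, N_CHM_PRESCRIPTIONS) for a, b, inst in TOP_PAIRS
    ]


def network_item_rows() -> list[dict]:
    """Item rows sufficient to annotate every endpoint of the printed pairs.

    Curcuma longa appears in the pair table but sits below the printed
    single-herb top ten, so its marginal count is not published; its node is
    annotated with the pair's prevalence (1.8%), a published lower bound.
    """
    from .stats import make_item_row

    rows = item_rows()
    known = {r["chm_id"] for r in rows}
    for a, b, inst in TOP_PAIRS:
        for name in (a, b):
            if name not in known:
                rows.append(make_item_row(name, "SH", inst, None, None, N_CHM_PRESCRIPTIONS))
                known.add(name)
    return rows


def chm_type_of(name: str) -> str:
    """HF/SH lookup over the printed tables (Curcuma is a single herb)."""
    hf = {n for n, *_ in TOP_HF}
    return "HF" if name in hf else "SH"
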