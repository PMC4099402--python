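"""Synthetic claims generator with planted prescription structure.

The generator emulates the statistical shape of nationwide TCM ambulatory
claims: multi-visit patients, up to three ordered ICD-9 codes with the
target diagnosis (PMS, 625.4) in first position for cohort visits, a
CHM/acupuncture/massage modality mix, and multi-item prescriptions built
from a dominant core formula, conditionally co-prescribed adjuvants, and a
long tail of low-probability items. Because every inclusion probability is
configured, the implied marginal, pair and conditional probabilities are
available in closed form (:class:`GroundTruth`), which is what makes
parameter-recovery testing of the mining pipeline possible.

Sampling model, per qualifying visit:

1. every core/baseline item enters the basket independently with its
   marginal probability;
2. each adjuvant rule ``(A, B, c)`` whose antecedent ``A`` is in the
   *marginal-pass* basket adds ``B`` with probability ``c`` — one pass, no
   chaining, so rule-added items never trigger further rules and the pair
   probability P(A ∩ B) stays closed-form;
3. duration and administrations/day are drawn once per prescription, doses
   per item from a normal truncated at zero.

A basket can come out empty (probability ``exp(-E[size])``-ish); such visits
are emitted as acupuncture-only so the record invariant (items nonempty iff
CHM modality) holds. They stay in the target-visit denominator and drop out
of the CHM cohort, like real acupuncture-only visits.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass
from math import prod
from pathlib import Path

import numpy as np
import yaml

from .model import ACUPUNCTURE, CHM, MASSAGE, ClaimsDataset, PrescriptionItem, VisitRecord

__all__ = ["GeneratorConfig", "GroundTruth", "generate_claims", "default_pms_config"]

TARGET_DX = "625.4"
DISTRACTOR_DX = ("625.3", "626.2", "306.4", "307.40", "780.52", "729.1")
_EPOCH = _dt.date(1998, 1, 1)
_DAYS = (_dt.date(2011, 12, 31) - _EPOCH).days + 1


class ConfigError(ValueError):
    """An invalid generator configuration."""


@dataclass
class GeneratorConfig:
    """Full specification of one synthetic claims population.

    ``core_items``/``baseline_items`` map chm_id to marginal inclusion
    probability (the split is purely descriptive; both are sampled the same
    way). ``adjuvant_rules`` are (antecedent, adjuvant, conditional
    probability) triples. ``catalog`` maps every chm_id to (display name,
    HF/SH type). ``dose_params`` holds per-item (mean, sd) in g/day.
    """

    n_patients: int
    mean_visits_per_patient: float
    p_target_dx: float
    p_extra_dx: float
    p_acu_massage: float
    core_items: dict[str, float]
    adjuvant_rules: list[tuple[str, str, float]]
    baseline_items: dict[str, float]
    catalog: dict[str, tuple[str, str]]
    dose_params: dict[str, tuple[float, float]]
    duration_choices: dict[int, float]
    admin_choices: dict[int, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if self.mean_visits_per_patient < 1:
            raise ConfigError("mean_visits_per_patient must be >= 1")
        for name in ("p_target_dx", "p_extra_dx", "p_acu_massage"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        overlap = set(self.core_items) & set(self.baseline_items)
        if overlap:
            raise ConfigError(f"items in both core and baseline maps: {sorted(overlap)}")
        for cid, p in self.marginal_config().items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"inclusion probability of {cid!r} must be in [0, 1], got {p}")
            if cid not in self.catalog:
                raise ConfigError(f"item {cid!r} missing from catalog")
        adjuvants = set()
        for a, b, c in self.adjuvant_rules:
            if a not in self.catalog or b not in self.catalog:
                raise ConfigError(f"rule ({a!r}, {b!r}) references uncatalogued items")
            if not 0.0 <= c <= 1.0:
                raise ConfigError(f"conditional probability of rule ({a}, {b}) out of [0, 1]")
            adjuvants.add(b)
        chained = adjuvants & {a for a, _, _ in self.adjuvant_rules}
        if chained:
            # would break the closed-form ground truth (no-chaining design)
            raise ConfigError(f"rule antecedents may not also be rule adjuvants: {sorted(chained)}")
        sampled = set(self.core_items) | set(self.baseline_items) | {b for _, b, _ in self.adjuvant_rules}
        for cid in sampled:
            if cid not in self.dose_params:
                raise ConfigError(f"item {cid!r} missing from dose_params")
        for name in ("duration_choices", "admin_choices"):
            weights = getattr(self, name)
            if not weights or any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
                raise ConfigError(f"{name} must be nonempty with nonnegative weights")

    def marginal_config(self) -> dict[str, float]:
        """Configured marginal inclusion probabilities (before rule effects)."""
        return {**self.core_items, **self.baseline_items}

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["adjuvant_rules"] = [list(r) for r in self.adjuvant_rules]
        d["catalog"] = {k: list(v) for k, v in self.catalog.items()}
        d["dose_params"] = {k: list(v) for k, v in self.dose_params.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        d["adjuvant_rules"] = [tuple(r) for r in d["adjuvant_rules"]]
        d["catalog"] = {k: tuple(v) for k, v in d["catalog"].items()}
        d["dose_params"] = {k: tuple(v) for k, v in d["dose_params"].items()}
        d["duration_choices"] = {int(k): v for k, v in d["duration_choices"].items()}
        d["admin_choices"] = {int(k): v for k, v in d["admin_choices"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Closed-form probabilities implied by a :class:`GeneratorConfig`.

    All probabilities are per sampled prescription, i.e. before the rare
    empty-basket draws are diverted to acupuncture-only visits.
    ``pair_probs[(a, b)] = marginal_probs[a] * conditional_probs[(a, b)]``
    holds by construction for every planted rule.
    """

    config: GeneratorConfig
    marginal_probs: dict[str, float]
    conditional_probs: dict[tuple[str, str], float]
    pair_probs: dict[tuple[str, str], float]
    expected_items_per_prescription: float
    n_qualifying_prescriptions: int = 0

    def to_json(self, path: str | Path) -> None:
        d = {
            "marginal_probs": self.marginal_probs,
            "conditional_probs": {f"{a}->{b}": p for (a, b), p in self.conditional_probs.items()},
            "pair_probs": {f"{a}&{b}": p for (a, b), p in self.pair_probs.items()},
            "expected_items_per_prescription": self.expected_items_per_prescription,
            "n_qualifying_prescriptions": self.n_qualifying_prescriptions,
            "seed": self.config.seed,
        }
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True), encoding="utf-8")


def ground_truth(config: GeneratorConfig) -> GroundTruth:
    """Derive the implied marginal, conditional and pair probabilities.

    With marginal probabilities ``p`` and rules ``(A, B, c)`` firing
    independently with probability ``p_A * c``:

    - P(B present) = 1 - (1 - p_B) * prod over rules targeting B of (1 - p_A c)
    - P(B | A present), for a rule antecedent A: as above but with the A-rule
      factor replaced by (1 - c) — the antecedent is known present.
    """
    marg = config.marginal_config()
    rules_by_target: dict[str, list[tuple[str, float]]] = {}
    for a, b, c in config.adjuvant_rules:
        rules_by_target.setdefault(b, []).append((a, c))

    def present_prob(b: str, given: str | None = None) -> float:
        p_b = marg.get(b, 0.0)
        factor = prod(
            (1 - c) if a == given else (1 - marg.get(a, 0.0) * c)
            for a, c in rules_by_target.get(b, [])
        )
        return 1 - (1 - p_b) * factor

    marginal = {cid: present_prob(cid) for cid in config.catalog}
    conditional: dict[tuple[str, str], float] = {}
    pair: dict[tuple[str, str], float] = {}
    for a, b, _c in config.adjuvant_rules:
        conditional[(a, b)] = present_prob(b, given=a)
        pair[(a, b)] = marg.get(a, 0.0) * conditional[(a, b)]
    return GroundTruth(
        config=config,
        marginal_probs=marginal,
        conditional_probs=conditional,
        pair_probs=pair,
        expected_items_per_prescription=sum(marginal.values()),
    )


def _sample_basket(config: GeneratorConfig, item_ids: list[str], probs: np.ndarray,
                   rng: np.random.Generator) -> set[str]:
    u = rng.random(len(item_ids))
    base = {item_ids[i] for i in np.nonzero(u < probs)[0]}
    added = set()
    for a, b, c in config.adjuvant_rules:
        if a in base and rng.random() < c:
            added.add(b)
    return base | added


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    # rejection at zero; for the g/day scales used the loop almost never repeats
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return round(x, 2)
    return round(max(mean, 0.01), 2)


def _weighted_choice(choices: dict[int, float], rng: np.random.Generator) -> int:
    keys = sorted(choices)
    w = np.array([choices[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=w / w.sum()))


def generate_claims(config: GeneratorConfig) -> tuple[ClaimsDataset, GroundTruth]:
    """Sample a full claims dataset; deterministic under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    truth = ground_truth(config)
    marg = config.marginal_config()
    item_ids = sorted(marg)
    probs = np.array([marg[i] for i in item_ids])

    visits: list[VisitRecord] = []
    n_qualifying = 0
    visit_no = 0
    for p in range(config.n_patients):
        patient_id = f"P{p + 1:06d}"
        n_visits = 1 + rng.poisson(config.mean_visits_per_patient - 1)
        for _ in range(n_visits):
            visit_no += 1
            visit_id = f"V{visit_no:07d}"
            date = _EPOCH + _dt.timedelta(days=int(rng.integers(0, _DAYS)))
            is_target = rng.random() < config.p_target_dx
            if is_target:
                dx = [TARGET_DX]
                if rng.random() < config.p_extra_dx:
                    dx.append(str(rng.choice(DISTRACTOR_DX)))
            else:
                n_dx = int(rng.integers(1, 4))
                dx = list(rng.choice(DISTRACTOR_DX, size=n_dx, replace=False))

            basket = _sample_basket(config, item_ids, probs, rng)
            if not basket:
                visits.append(
                    VisitRecord(visit_id, patient_id, date, tuple(dx),
                                frozenset({ACUPUNCTURE}), ())
                )
                continue

            modality = {CHM}
            if rng.random() < config.p_acu_massage:
                modality.add(ACUPUNCTURE if rng.random() < 0.5 else MASSAGE)
            duration = _weighted_choice(config.duration_choices, rng)
            admin = _weighted_choice(config.admin_choices, rng)
            items = []
            for cid in sorted(basket):
                mean_d, sd_d = config.dose_params[cid]
                name, kind = config.catalog[cid]
                items.append(
                    PrescriptionItem(cid, name, kind,
                                     _truncated_normal(mean_d, sd_d, rng),
                                     duration, admin)
                )
            if is_target and len(dx) == 1 and modality == {CHM}:
                n_qualifying += 1
            visits.append(
                VisitRecord(visit_id, patient_id, date, tuple(dx),
                            frozenset(modality), tuple(items))
            )

    truth.n_qualifying_prescriptions = n_qualifying
    dataset = ClaimsDataset(visits=visits, item_catalog=dict(config.catalog))
    return dataset, truth


def default_pms_config(seed: int = 0, n_patients: int = 4000) -> GeneratorConfig:
    """The default synthetic PMS population.

    Calibrated to the population the pipeline is meant to analyze: a
    dominant core formula (JWXYS-like, marginal 37.5%), four further
    formulas, ten named single herbs whose implied marginals track the
    published prevalence ladder (rule effects included), a 26-item adjuvant
    tail bringing the expected prescription size to ~5.4 items, ~2.5 visits
    per patient, a 3.4% acupuncture/massage admixture, and dosing frequency
    massed on three times daily (89%). HF doses average ~4 g/day and SH
    ~1.3 g/day, reproducing the formula/single-herb dose-scale gap.
    """
    hf = {
        "HF001": ("Jia-Wei-Xiao-Yao-San", 0.375, 4.87),
        "HF002": ("Dang-Gui-Shao-Yao-San", 0.149, 4.34),
        "HF003": ("Gui-Zhi-Fu-Ling-Wan", 0.090, 3.87),
        "HF004": ("Wen-Jing-Tang", 0.081, 4.25),
        "HF005": ("Shao-Fu-Zhu-Yu-Tang", 0.072, 3.97),
    }
    sh = {
        "SH001": ("Cyperus rotundus", 0.056, 1.38),
        "SH002": ("Leonurus heterophyllus", 0.060, 1.33),
        "SH003": ("Corydalis yanhusuo", 0.057, 1.28),
        "SH004": ("Salvia miltiorrhiza", 0.054, 1.30),
        "SH005": ("Eucommia ulmoides", 0.074, 1.26),
        "SH006": ("Scutellaria baicalensis", 0.037, 1.30),
        "SH007": ("Dipsacus asperoides", 0.047, 1.17),
        "SH008": ("Cuscuta chinensis", 0.046, 1.44),
        "SH009": ("Pueraria lobata", 0.045, 1.33),
        "SH010": ("Paeonia suffruticosa", 0.044, 1.43),
        "SH011": ("Curcuma longa", 0.018, 1.35),
    }
    # conditional co-prescription with the core formula; chosen so the implied
    # single-herb marginals land near the published prevalence ladder
    rules = [
        ("HF001", "SH001", 0.35),
        ("HF001", "SH002", 0.26),
        ("HF001", "SH003", 0.16),
        ("HF001", "SH004", 0.11),
        ("HF001", "SH006", 0.07),
    ]
    baseline = {f"SH{i:03d}": (f"Adjuvant herb {i}", 0.145, 1.30) for i in range(12, 38)}

    catalog = {cid: (name, "HF") for cid, (name, _, _) in hf.items()}
    catalog |= {cid: (name, "SH") for cid, (name, _, _) in {**sh, **baseline}.items()}
    dose_params = {cid: (dose, 1.0 if cid.startswith("HF") else 0.35)
                   for cid, (_, _, dose) in {**hf, **sh, **baseline}.items()}
    return GeneratorConfig(
        n_patients=n_patients,
        mean_visits_per_patient=2.5,
        p_target_dx=0.5,
        p_extra_dx=0.10,
        p_acu_massage=0.034,
        core_items={cid: p for cid, (_, p, _) in {**hf, **sh}.items()},
        adjuvant_rules=rules,
        baseline_items={cid: p for cid, (_, p, _) in baseline.items()},
        catalog=catalog,
        dose_params=dose_params,
        duration_choices={3: 0.10, 5: 0.15, 6: 0.20, 7: 0.45, 10: 0.07, 14: 0.03},
        admin_choices={2: 0.026, 3: 0.890, 4: 0.084},
        seed=seed,
    )
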