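"""End-to-end orchestration: simulate/read -> cohort -> stats -> mine -> network.

One :func:`run_pipeline` call executes every stage, writes all tabular and
graph artifacts into an output directory, and finishes with a JSON manifest
(config echo, stage counts, SHA-256 of every artifact). Identical config and
seed produce byte-identical artifacts and therefore identical manifest
hashes. Any stage failure aborts with the stage name and removes the partial
outputs of the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import network as net
from . import stats
from .cohort import CohortConfig, cohort_summary, select_cohort
from .mining import MiningConfig, association_rules, frequent_itemsets, transactions_from_cohort, undirected_pairs
from .model import read_claims, write_claims, write_table
from .simulate import GeneratorConfig, generate_claims

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One reproducible run: either input CSV paths or a generator config."""

    out_dir: str | Path
    visits_path: str | Path | None = None
    items_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    mining: MiningConfig = field(default_factory=MiningConfig)
    top_hf: int = 5
    top_sh: int = 10
    top_pairs: int = 10
    network_from: str = "pairs"  # "pairs" (top-k by frequency) or "rules"

    def __post_init__(self) -> None:
        have_paths = self.visits_path is not None and self.items_path is not None
        if have_paths == (self.generator is not None):
            raise ValueError("provide exactly one of (visits_path+items_path) or generator")
        if self.network_from not in ("pairs", "rules"):
            raise ValueError("network_from must be 'pairs' or 'rules'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        written.append(path)
        return path

    stage = "input"
    try:
        if config.generator is not None:
            data, truth = generate_claims(config.generator)
            emit("visits.csv", lambda p: write_claims(data, p, out / "items.csv"))
            written.append(out / "items.csv")
            emit("generator_config.yaml", config.generator.to_yaml)
            emit("ground_truth.json", truth.to_json)
        else:
            data = read_claims(config.visits_path, config.items_path)

        stage = "cohort"
        cohort = select_cohort(data, config.cohort)
        summary = cohort_summary(cohort)
        logger.info(
            "cohort: %d target-diagnosis visits, %d CHM prescriptions (share %s%%), %d patients",
            summary["n_all_target_visits"], summary["n_chm_prescriptions"],
            summary["chm_share_pct"], summary["n_patients"],
        )
        emit("cohort_summary.json", lambda p: p.write_text(
            json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"))

        stage = "stats"
        item_rows = stats.item_prevalence(cohort)
        pair_rows = stats.pair_prevalence(cohort)
        hf_rows = [r for r in item_rows if r["chm_type"] == "HF"][: config.top_hf]
        sh_rows = [r for r in item_rows if r["chm_type"] == "SH"][: config.top_sh]
        emit("table1_hf.csv", lambda p: write_table(hf_rows, p, stats.ITEM_COLUMNS))
        emit("table2_sh.csv", lambda p: write_table(sh_rows, p, stats.ITEM_COLUMNS))
        emit("table3_pairs.csv", lambda p: write_table(
            pair_rows[: config.top_pairs], p, stats.PAIR_COLUMNS))
        size = stats.prescription_size_stats(cohort)
        dosing = stats.dosing_frequency_distribution(cohort)
        share = stats.combo_type_share(pair_rows[: config.top_pairs], data.item_catalog)
        emit("summary_stats.json", lambda p: p.write_text(json.dumps({
            "mean_items_per_prescription": size["mean_items"],
            "size_histogram": {str(k): v for k, v in size["histogram"].items()},
            "dosing_frequency_pct": {str(k): v for k, v in dosing.items()},
            "top_pair_type_share_pct": share,
        }, indent=2, sort_keys=True), encoding="utf-8"))

        stage = "mine"
        transactions = transactions_from_cohort(cohort)
        itemsets = frequent_itemsets(transactions, config.mining)
        rules = association_rules(itemsets, len(transactions), config.mining)
        sig_pairs = undirected_pairs(rules, itemsets)
        emit("itemsets.csv", lambda p: write_table(
            [{"items": ";".join(s.canonical()), "count": s.count, "support": round(s.support, 6)}
             for s in itemsets], p, ["items", "count", "support"]))
        emit("rules.csv", lambda p: write_table(
            [{"antecedent": ";".join(sorted(r.antecedent)),
              "consequent": ";".join(sorted(r.consequent)),
              "count": r.count, "support": round(r.support, 6),
              "confidence": round(r.confidence, 6)} for r in rules],
            p, ["antecedent", "consequent", "count", "support", "confidence"]))
        emit("pairs_significant.csv", lambda p: write_table(
            [{**r, "support": round(r["support"], 6),
              "confidence_a_to_b": _round_opt(r["confidence_a_to_b"]),
              "confidence_b_to_a": _round_opt(r["confidence_b_to_a"])} for r in sig_pairs],
            p, ["chm_a", "chm_b", "count", "support", "confidence_a_to_b", "confidence_b_to_a"]))

        stage = "network"
        if config.network_from == "rules":
            edge_rows = [
                {"chm_a": r["chm_a"], "chm_b": r["chm_b"], "instances": r["count"],
                 "prevalence_pct": 100.0 * r["support"]}
                for r in sorted(sig_pairs, key=lambda r: -r["count"])
            ]
        else:
            edge_rows = pair_rows
        graph = net.build_network(item_rows, edge_rows, config.top_pairs)
        core = net.identify_core(graph) if graph.number_of_nodes() else None
        emit("network.graphml", lambda p: net.export_graph(graph, p, "graphml"))
        emit("network_edges.csv", lambda p: net.export_graph(graph, p, "edge-list"))

        stage = "manifest"
        manifest = {
            "seed": config.generator.seed if config.generator is not None else None,
            "cohort_summary": summary,
            "mining": {"min_support": config.mining.min_support,
                       "min_confidence": config.mining.min_confidence,
                       "max_itemset_size": config.mining.max_itemset_size},
            "top_k": {"hf": config.top_hf, "sh": config.top_sh, "pairs": config.top_pairs},
            "counts": {"items": len(item_rows), "pairs": len(pair_rows),
                       "frequent_itemsets": len(itemsets), "rules": len(rules),
                       "significant_pairs": len(sig_pairs),
                       "network_nodes": graph.number_of_nodes(),
                       "network_edges": graph.number_of_edges()},
            "core_chm": core,
            "artifacts": {p.name: _sha256(p) for p in sorted(written)},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc


def _round_opt(x: float | None) -> float | None:
    return None if x is None else round(x, 6)
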