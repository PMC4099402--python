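"""Co-prescription network construction and core-treatment identification.

Nodes are CHM products sized by prevalence; undirected edges connect CHM
that appear together in prescriptions, weighted by the co-occurrence count.
The "core treatment" — the product around which the others act as adjuvants
— is operationalized as the node maximizing weighted degree (sum of incident
co-occurrence counts), with prevalence and then identifier as tie-breaks.
Visual inspection of such networks in the CHM prescribing literature points
to the same hub this criterion selects.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import networkx as nx

__all__ = [
    "build_network",
    "weighted_degree",
    "identify_core",
    "export_graph",
    "import_graph",
    "plot_network",
]


def build_network(
    item_rows: Sequence[dict], pair_rows: Sequence[dict], top_k_pairs: int = 10
) -> nx.Graph:
    """Graph of the top-k co-prescription pairs.

    ``pair_rows`` must already be sorted by instances descending (the
    contract of :func:`herbnet.stats.pair_prevalence`); nodes are the union
    of the selected pairs' endpoints annotated with prevalence and type from
    ``item_rows``. An endpoint missing from ``item_rows`` means the two
    inputs came from different cohorts and is an error.
    """
    counts = [r["instances"] for r in pair_rows]
    if counts != sorted(counts, reverse=True):
        raise ValueError("pair_rows must be sorted by instances descending")
    attrs = {r["chm_id"]: r for r in item_rows}
    g = nx.Graph(top_k_pairs=top_k_pairs)
    for row in list(pair_rows)[:top_k_pairs]:
        a, b = row["chm_a"], row["chm_b"]
        if a == b:
            raise ValueError(f"self-loop pair {a!r}")
        for endpoint in (a, b):
            if endpoint not in attrs:
                raise ValueError(
                    f"pair endpoint {endpoint!r} absent from the item prevalence table"
                )
            if endpoint not in g:
                g.add_node(
                    endpoint,
                    prevalence_pct=float(attrs[endpoint]["prevalence_pct"]),
                    chm_type=str(attrs[endpoint]["chm_type"]),
                )
        g.add_edge(a, b, count=int(row["instances"]))
    return g


def weighted_degree(network: nx.Graph, chm_id: str) -> int:
    """Sum of incident edge counts; 0 for an isolated node."""
    if chm_id not in network:
        raise KeyError(f"unknown node {chm_id!r}")
    return sum(d["count"] for _, _, d in network.edges(chm_id, data=True))


def identify_core(network: nx.Graph) -> str:
    """The node maximizing weighted degree (ties: prevalence, then id)."""
    if network.number_of_nodes() == 0:
        raise ValueError("cannot identify a core in an empty network")
    return min(
        network.nodes,
        key=lambda n: (
            -weighted_degree(network, n),
            -network.nodes[n]["prevalence_pct"],
            n,
        ),
    )


def export_graph(network: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML or a three-column edge list.

    GraphML preserves node attributes (prevalence_pct, chm_type) and the
    edge count, so :func:`import_graph` reproduces the network exactly; the
    edge list (chm_a,chm_b,count) is for quick inspection and drops isolated
    nodes and node attributes.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "edge-list":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["chm_a", "chm_b", "count"])
            for a, b, d in sorted(network.edges(data=True), key=lambda e: (-e[2]["count"], e[0], e[1])):
                w.writerow([a, b, d["count"]])
    else:
        raise ValueError(f"unknown export format {format!r}; use 'graphml' or 'edge-list'")


def import_graph(path: str | Path) -> nx.Graph:
    """Read a GraphML file written by :func:`export_graph`."""
    g = nx.read_graphml(path)
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(n, prevalence_pct=float(d["prevalence_pct"]), chm_type=str(d["chm_type"]))
    for a, b, d in g.edges(data=True):
        out.add_edge(a, b, count=int(d["count"]))
    return out


def plot_network(network: nx.Graph, path: str | Path, seed: int = 0) -> None:
    """Optional rendering: force-directed layout, node size ∝ prevalence,
    edge width ∝ co-occurrence count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(network, seed=seed)
    sizes = [60 * network.nodes[n]["prevalence_pct"] for n in network.nodes]
    counts = [d["count"] for _, _, d in network.edges(data=True)]
    max_count = max(counts, default=1)
    widths = [0.5 + 4.0 * c / max_count for c in counts]
    fig, ax = plt.subplots(figsize=(7, 7))
    nx.draw_networkx(network, pos=pos, ax=ax, node_size=sizes, width=widths,
                     node_color="#8fbcd4", edge_color="#666666", font_size=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
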