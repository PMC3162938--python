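"""Downstream comparison of refined regulatory networks.

Covers the summaries reported for each condition's network (node/edge
counts, degree tables and the qualitative small-degree-abundance check of
scale-free topology), the differential decomposition of two condition
networks into a common subnetwork plus condition-specific edges, averaged
expression curves over named gene groups (e.g. PSI-related vs. PSII-related
genes), and export to Cytoscape-friendly formats.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, normalize_gene_id

__all__ = [
    "GeneNetwork",
    "DifferentialResult",
    "summarize_network",
    "differential_networks",
    "degree_rank_table",
    "degree_distribution_check",
    "average_group_expression",
    "export_network",
    "import_network",
]

Edge = tuple[str, str]


class GeneNetwork:
    """A refined directed, weighted regulatory network for one condition.

    Wraps a :class:`networkx.DiGraph` whose edges carry ``weight`` (the
    regulatory ability ``b_i``), ``sign`` ("activates"/"represses") and
    ``condition`` attributes, and whose nodes carry an ``is_tf`` flag.
    Isolated fitted targets (all candidate regulators pruned away) remain
    in the node set.
    """

    def __init__(self, condition: str, graph: nx.DiGraph | None = None):
        self.condition = condition
        self.graph = graph if graph is not None else nx.DiGraph()
        self.fits: dict = {}

    @classmethod
    def from_edges(
        cls,
        condition: str,
        edges: Iterable[tuple],
        nodes: Iterable[str] = (),
        tf_ids: Iterable[str] = (),
    ) -> "GeneNetwork":
        """Build from ``(tf, target, weight, sign)`` tuples (sign optional)."""
        net = cls(condition)
        tf_ids = {normalize_gene_id(t) for t in tf_ids}
        for node in nodes:
            net.graph.add_node(normalize_gene_id(node))
        for item in edges:
            tf, target = normalize_gene_id(item[0]), normalize_gene_id(item[1])
            weight = float(item[2]) if len(item) > 2 else 1.0
            sign = item[3] if len(item) > 3 else ("activates" if weight > 0 else "represses")
            net.graph.add_edge(tf, target, weight=weight, sign=sign, condition=condition)
            tf_ids.add(tf)
        for node in net.graph.nodes:
            net.graph.nodes[node]["is_tf"] = node in tf_ids
        return net

    def edge_set(self) -> set[Edge]:
        return set(self.graph.edges())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def total_degree(self, node: str) -> int:
        """In-degree + out-degree (one connectivity number per gene)."""
        node = normalize_gene_id(node)
        if node not in self.graph:
            return 0
        return self.graph.in_degree(node) + self.graph.out_degree(node)


@dataclass(frozen=True)
class DifferentialResult:
    """Three-way decomposition of two condition networks' edge sets.

    ``common`` holds the interactions found under both conditions (the
    inherent-regulation subnetwork); ``only_a``/``only_b`` are the
    condition-specific differential networks.  Edge identity is the
    (TF, target) pair; pairs whose fitted sign differs between conditions
    are still common but listed in ``sign_conflicts``.
    """

    condition_a: str
    condition_b: str
    common: frozenset[Edge]
    only_a: frozenset[Edge]
    only_b: frozenset[Edge]
    sign_conflicts: frozenset[Edge] = frozenset()


def summarize_network(net: GeneNetwork) -> dict:
    """Node/edge counts, per-node total degree, and a degree histogram."""
    degrees = {n: net.total_degree(n) for n in net.graph.nodes}
    return {
        "condition": net.condition,
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "degrees": degrees,
        "degree_histogram": dict(sorted(Counter(degrees.values()).items())),
    }


def differential_networks(a: GeneNetwork, b: GeneNetwork) -> DifferentialResult:
    """Match interactions across conditions: common vs. condition-specific.

    The three edge sets are pairwise disjoint and partition each input:
    ``common | only_a`` equals A's edges and ``common | only_b`` equals B's.
    """
    ea, eb = a.edge_set(), b.edge_set()
    common = ea & eb
    conflicts = {
        e
        for e in common
        if a.graph.edges[e].get("sign") != b.graph.edges[e].get("sign")
    }
    return DifferentialResult(
        condition_a=a.condition,
        condition_b=b.condition,
        common=frozenset(common),
        only_a=frozenset(ea - eb),
        only_b=frozenset(eb - ea),
        sign_conflicts=frozenset(conflicts),
    )


def degree_rank_table(
    nets: tuple[GeneNetwork, GeneNetwork],
    genes_of_interest: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-gene total degree in each condition, sorted by the first.

    Supports hub comparison across conditions (rank reversals between the
    two degree columns identify condition-specific hubs).  Requested genes
    absent from both networks appear with degree 0 and ``absent=True``.
    """
    a, b = nets
    if genes_of_interest is None:
        genes = sorted(set(a.graph.nodes) | set(b.graph.nodes))
    else:
        genes = [normalize_gene_id(g) for g in genes_of_interest]
    rows = []
    for g in genes:
        da, db = a.total_degree(g), b.total_degree(g)
        rows.append(
            {
                "gene": g,
                f"degree_{a.condition}": da,
                f"degree_{b.condition}": db,
                "absent": g not in a.graph and g not in b.graph,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values(
            [f"degree_{a.condition}", "gene"], ascending=[False, True]
        ).reset_index(drop=True)
    return table


def degree_distribution_check(net: GeneNetwork) -> dict:
    """Degree histogram plus the small-degree-abundance indicator.

    The indicator is True when node counts are non-increasing across the
    occupied degree bins in increasing degree order — the qualitative
    signature that small-degree nodes are most abundant and high-degree
    hubs rare (as opposed to a random graph's mode at intermediate degree).
    No power-law exponent is fitted.
    """
    if net.n_nodes < 5:
        raise ValueError("degree distribution check needs at least 5 nodes")
    hist = summarize_network(net)["degree_histogram"]
    counts = [hist[d] for d in sorted(hist)]
    indicator = all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))
    return {
        "degree_histogram": hist,
        "small_degree_most_abundant": indicator,
    }


def average_group_expression(
    dataset: ExpressionDataset,
    groups: Mapping[str, Iterable[str]],
    restrict_to: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Replicate-averaged then gene-averaged expression per named group.

    ``restrict_to`` optionally intersects every group with a node set
    (e.g. a differential network's genes) before averaging, so curves can
    be limited to genes that are actually regulated in the networks under
    comparison.  Returns a time x group DataFrame; empty groups yield
    all-NaN columns with a warning.
    """
    import warnings

    restrict = (
        {normalize_gene_id(g) for g in restrict_to} if restrict_to is not None else None
    )
    curves: dict[str, np.ndarray] = {}
    for name, members in groups.items():
        ids = {normalize_gene_id(g) for g in members}
        if restrict is not None:
            ids &= restrict
        ids = sorted(g for g in ids if g in dataset)
        if not ids:
            warnings.warn(f"group {name!r} is empty after restriction", UserWarning)
            curves[name] = np.full(dataset.times.shape, np.nan)
            continue
        curves[name] = np.mean([dataset[g].mean_profile() for g in ids], axis=0)
    return pd.DataFrame(curves, index=pd.Index(dataset.times, name="time_h"))


# ---------------------------------------------------------------------------
# export / import

_FORMATS = ("sif", "graphml", "tsv")


def export_network(net: GeneNetwork, path, fmt: str | None = None) -> Path:
    """Write a network as SIF, GraphML or an edge-list TSV.

    SIF lines read ``TF activates|represses target`` (the Cytoscape
    convention); GraphML carries weight, sign and condition attributes and
    round-trips exactly through :func:`import_network`.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown network format {fmt!r}; choose from {_FORMATS}")
    if fmt == "sif":
        lines = [
            f"{u}\t{d.get('sign', 'activates')}\t{v}"
            for u, v, d in sorted(net.graph.edges(data=True))
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path, named_key_ids=True)
    else:
        frame = pd.DataFrame(
            [
                {
                    "tf_id": u,
                    "target_id": v,
                    "b_hat": d.get("weight", 1.0),
                    "sign": d.get("sign", "activates"),
                    "condition": d.get("condition", net.condition),
                }
                for u, v, d in sorted(net.graph.edges(data=True))
            ],
            columns=["tf_id", "target_id", "b_hat", "sign", "condition"],
        )
        frame.to_csv(path, sep="\t", index=False)
    return path


def import_network(path, fmt: str | None = None, condition: str = "") -> GeneNetwork:
    """Read a network written by :func:`export_network`."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        digraph = nx.DiGraph()
        digraph.add_nodes_from(graph.nodes(data=True))
        digraph.add_edges_from(graph.edges(data=True))
        conditions = {d.get("condition") for _, _, d in digraph.edges(data=True)}
        label = condition or (conditions.pop() if len(conditions) == 1 else "")
        return GeneNetwork(label, digraph)
    if fmt == "sif":
        edges = []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            tf, sign, target = line.split("\t")
            edges.append((tf, target, 1.0 if sign == "activates" else -1.0, sign))
        return GeneNetwork.from_edges(condition, edges)
    if fmt == "tsv":
        frame = pd.read_csv(path, sep="\t")
        label = condition or (
            frame["condition"].iloc[0] if len(frame) else ""
        )
        edges = [
            (row.tf_id, row.target_id, row.b_hat, row.sign)
            for row in frame.itertuples()
        ]
        return GeneNetwork.from_edges(label, edges)
    raise ValueError(f"unknown network format {fmt!r}; choose from {_FORMATS}")
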