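"""Semantic-map extraction: minimum spanning tree, maximally regular graph,
hub ranking and fracture-subgroup comparison.

The MST of the Auto-CM distance matrix is the backbone of the semantic map:
it keeps, among all spanning trees, the one of least total distance, so each
variable stays attached to its strongest associations.  The maximally
regular graph (MRG) then adds back the k shortest non-tree edges that
maximise a regularity score H = R/(1+k), where R counts the cycles of a
minimum cycle basis whose member nodes all share the same degree ("regular
cyclic microstructures"); the MRG exposes redundant, strongly interlocked
variable clusters that the tree filter hides.  All tie-breaking is
lexicographic on node labels, so every map is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .autocm import AutoCMConfig, DistanceMatrix, train_autocm, weights_to_distances
from .clinical import VFX_NO, VFX_YES, assign_fracture_group
from .cohort import CONTINUOUS, CohortTable
from .scaling import expand_complementary

MST = "MST"
MRG = "MRG"


@dataclass
class SemanticGraph:
    """Weighted undirected labelled graph (MST or MRG) with hub annotations."""

    graph: nx.Graph
    kind: str  # MST | MRG

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((u, v))) for u, v in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return int(self.graph.degree[node])

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node1": u, "node2": v, "distance": d}
            for (u, v), d in sorted(
                ((tuple(sorted((a, b))), w["distance"]) for a, b, w in self.graph.edges(data=True))
            )
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "distance"])


def _sorted_edges(d: DistanceMatrix) -> list[tuple[float, str, str]]:
    """All off-diagonal edges sorted by (distance, label pair)."""
    edges = []
    n = len(d.labels)
    for i in range(n):
        for j in range(i + 1, n):
            u, v = sorted((d.labels[i], d.labels[j]))
            edges.append((float(d.d[i, j]), u, v))
    edges.sort()
    return edges


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def minimum_spanning_tree(d: DistanceMatrix) -> SemanticGraph:
    """Kruskal MST with lexicographic tie-breaking on edge labels."""
    if len(d.labels) < 2:
        raise ValueError("need at least 2 nodes")
    if not np.all(np.isfinite(d.d)):
        raise ValueError("distance matrix contains non-finite entries")
    g = nx.Graph()
    g.add_nodes_from(sorted(d.labels))
    uf = _UnionFind(d.labels)
    for dist, u, v in _sorted_edges(d):
        if uf.union(u, v):
            g.add_edge(u, v, distance=dist)
            if g.number_of_edges() == len(d.labels) - 1:
                break
    sg = SemanticGraph(graph=g, kind=MST)
    find_hubs(sg)
    return sg


def regularity_score(g: SemanticGraph | nx.Graph, added_edge_count: int) -> float:
    """H = R/(1+k): regular basis cycles penalised by the added-edge count.

    R counts cycles of a minimum cycle basis whose member nodes all have the
    same degree within the graph; trees score 0.
    """
    graph = g.graph if isinstance(g, SemanticGraph) else g
    if graph.number_of_nodes() and not nx.is_connected(graph):
        raise ValueError("graph must be connected")
    if added_edge_count < 0:
        raise ValueError("added_edge_count must be >= 0")
    basis = nx.minimum_cycle_basis(graph)
    degrees = dict(graph.degree)
    r = sum(1 for cycle in basis if len({degrees[n] for n in cycle}) == 1)
    return r / (1.0 + added_edge_count)


def maximally_regular_graph(
    d: DistanceMatrix,
    mst: SemanticGraph | None = None,
    k_max: int | None = None,
) -> SemanticGraph:
    """MST plus the k shortest non-tree edges maximising the regularity score.

    Scans k = 0..k_max (default: node count), adding non-tree edges in the
    same (distance, label) order as Kruskal, and returns the graph with the
    highest H; ties resolve to the smallest k, so k = 0 reproduces the MST.
    """
    mst = mst or minimum_spanning_tree(d)
    tree_edges = mst.edge_set
    candidates = [
        (dist, u, v)
        for dist, u, v in _sorted_edges(d)
        if (u, v) not in tree_edges
    ]
    if k_max is None:
        k_max = len(d.labels)
    k_max = min(k_max, len(candidates))

    g = mst.graph.copy()
    best_k, best_h = 0, 0.0
    snapshots = {0: g.copy()}
    for k in range(1, k_max + 1):
        dist, u, v = candidates[k - 1]
        g.add_edge(u, v, distance=dist)
        h = regularity_score(g, k)
        snapshots[k] = g.copy()
        if h > best_h:
            best_h, best_k = h, k
    sg = SemanticGraph(graph=snapshots[best_k], kind=MRG)
    find_hubs(sg)
    return sg


def find_hubs(g: SemanticGraph) -> list[str]:
    """Nodes ranked by degree (descending, ties lexicographic).

    Writes ``degree`` and ``hub_rank`` (1 = most connected) back onto the
    graph's node attributes and returns the ranked label list.
    """
    ranked = sorted(g.graph.nodes, key=lambda n: (-g.graph.degree[n], n))
    for rank, node in enumerate(ranked, start=1):
        g.graph.nodes[node]["degree"] = int(g.graph.degree[node])
        g.graph.nodes[node]["hub_rank"] = rank
    return ranked


def build_maps(
    table: CohortTable, autocm_config: AutoCMConfig | None = None
) -> tuple[SemanticGraph, SemanticGraph, DistanceMatrix]:
    """Preprocess → train Auto-CM → (MST, MRG, distances) for one table."""
    scaled = expand_complementary(table)
    wm = train_autocm(scaled, autocm_config)
    dm = weights_to_distances(wm)
    mst = minimum_spanning_tree(dm)
    mrg = maximally_regular_graph(dm, mst)
    return mst, mrg, dm


def subgroup_maps(
    table: CohortTable,
    autocm_config: AutoCMConfig | None = None,
    fracture_variable: str = "Fracture",
    sdi_variable: str = "SDI",
) -> dict[str, SemanticGraph]:
    """Independent MRG per fracture subgroup (SDI > 5 vs the rest).

    The fracture-status variable is dropped inside each subgroup (the split
    itself encodes it); any other variable left constant within a subgroup is
    reported as an error listing the offenders.
    """
    groups = np.array([assign_fracture_group(s) for s in table.values(sdi_variable)])
    out: dict[str, SemanticGraph] = {}
    for label in (VFX_YES, VFX_NO):
        mask = groups == label
        if mask.sum() < 2:
            raise ValueError(
                f"subgroup {label} has {int(mask.sum())} record(s); need at least 2"
            )
        sub = table.subset(mask)
        if fracture_variable in sub.schema.names:
            sub = sub.drop_variables(fracture_variable)
        constant = [
            v.name
            for v in sub.schema.variables
            if v.kind == CONTINUOUS and np.unique(sub.values(v.name)).size < 2
        ]
        if constant:
            raise ValueError(
                f"subgroup {label}: constant column(s) {constant}; cannot scale"
            )
        _, mrg, _ = build_maps(sub, autocm_config)
        out[label] = mrg
    return out


def compare_maps(a: SemanticGraph, b: SemanticGraph) -> dict[str, float]:
    """Edge-set Jaccard index and per-graph edge counts.

    Edges are unordered label pairs; weights are ignored for identity.
    """
    ea, eb = a.edge_set, b.edge_set
    union = ea | eb
    if not union:
        raise ValueError("both graphs are edgeless; Jaccard undefined")
    return {
        "jaccard": len(ea & eb) / len(union),
        "edges_a": len(ea),
        "edges_b": len(eb),
        "shared_edges": len(ea & eb),
    }


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_graphml(g: SemanticGraph, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g.graph, path)


def write_dot(g: SemanticGraph, path: str | Path) -> None:
    """Minimal Graphviz DOT serialisation (distance as edge label)."""
    lines = [f'graph "{g.kind}" {{']
    for node in sorted(g.graph.nodes):
        rank = g.graph.nodes[node].get("hub_rank", "")
        lines.append(f'  "{node}" [hub_rank="{rank}"];')
    for u, v, data in sorted(g.graph.edges(data=True)):
        lines.append(f'  "{u}" -- "{v}" [weight="{data["distance"]:.6f}"];')
    lines.append("}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_edgelist_csv(g: SemanticGraph, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    g.to_edge_frame().to_csv(path, index=False)


def read_graphml(path: str | Path, kind: str = MST) -> SemanticGraph:
    return SemanticGraph(graph=nx.read_graphml(path), kind=kind)


def plot_semantic_graph(g: SemanticGraph, path: str | Path, seed: int = 0) -> None:
    """Basic spring-layout rendering (layout aesthetics are not a goal)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = nx.spring_layout(g.graph, seed=seed)
    fig, ax = plt.subplots(figsize=(12, 9))
    nx.draw_networkx(
        g.graph, pos=pos, ax=ax, node_size=600, font_size=7,
        node_color="#bcd4e6", edge_color="#777777",
    )
    ax.set_title(f"{g.kind} semantic map")
    ax.axis("off")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
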