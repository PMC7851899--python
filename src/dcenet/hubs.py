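"""Hub-gene extraction from the differentially correlated edge graph.

The DCE graph is an unweighted, undirected graph with one edge per called
DCE (sign kept as an edge attribute).  Hubs are the top-k nodes by plain
degree -- an edge count, matching the "Degree" method of cytoHubba -- with
ties broken alphabetically so rankings are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from dcenet.differential_edges import DceSet
from dcenet.errors import ValidationError


@dataclass(frozen=True)
class HubList:
    """Ordered (gene, degree) pairs, degrees non-increasing."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self):
        degrees = [d for _, d in self.entries]
        if any(degrees[i] < degrees[i + 1] for i in range(len(degrees) - 1)):
            raise ValidationError("hub list degrees are not non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"rank": i + 1, "gene_symbol": g, "degree": d}
                for i, (g, d) in enumerate(self.entries)
            ],
            columns=["rank", "gene_symbol", "degree"],
        )


def build_dce_graph(dce_set: DceSet) -> nx.Graph:
    """One node per gene touched by a DCE, one edge per record (sign attr)."""
    graph = nx.Graph(cohort=dce_set.cohort_label)
    for edge, rec in dce_set.records.items():
        graph.add_edge(edge[0], edge[1], sign=rec.sign, delta=rec.delta)
    return graph


def rank_hubs_by_degree(
    graph: nx.Graph, k: int = 50, include_ties: bool = False
) -> HubList:
    """Top-k nodes by degree; ties by gene symbol, ascending.

    With ``include_ties`` every node whose degree equals the degree at rank k
    is kept, so the list may exceed k.
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    ranked = sorted(graph.nodes, key=lambda g: (-graph.degree[g], g))
    top = ranked[:k]
    if include_ties and len(ranked) > k and top:
        cut = graph.degree[top[-1]]
        top = [g for g in ranked if graph.degree[g] >= cut]
    return HubList(tuple((g, int(graph.degree[g])) for g in top))


def overlap_hub_lists(hubs_a: HubList, hubs_b: HubList) -> list[str]:
    """Sorted intersection of the two hub lists' gene symbols."""
    return sorted(set(hubs_a.genes()) & set(hubs_b.genes()))


def export_sif(graph: nx.Graph, path, hubs: HubList | None = None,
               induced: bool = True) -> None:
    """Write the graph as SIF text: ``node1 <TAB> relation <TAB> node2``.

    The relation is ``dce_gain`` for +1 edges and ``dce_loss`` for -1 edges.
    When ``hubs`` is given and ``induced`` is true, only the subgraph induced
    on the hub genes is written; with ``induced`` false the full graph is
    written (hubs then only document intent).  Edges are emitted in sorted
    order so output is deterministic.
    """
    if hubs is not None and induced:
        graph = graph.subgraph(hubs.genes())
    lines = []
    for u, v, data in sorted(graph.edges(data=True)):
        relation = "dce_gain" if data.get("sign", 1) > 0 else "dce_loss"
        a, b = (u, v) if u < v else (v, u)
        lines.append(f"{a}\t{relation}\t{b}")
    lines.sort()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
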