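"""PPI subgraphs, degree-based hub ranking, hub subnetworks, Venn overlaps.

Hub genes are the top-degree nodes of the protein-protein-interaction
subgraph induced by the differentially expressed mRNAs (high-confidence
edges only). The hub subnetwork keeps exactly the ceRNA axes whose mRNA is
a hub, recovering the lncRNAs and miRNAs that putatively regulate them.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import pandas as pd

from .cerna import CeRNAAxis, build_network

__all__ = [
    "HubReport",
    "build_ppi_subgraph",
    "rank_hubs",
    "reconstruct_subnetwork",
    "overlap_analysis",
    "network_summary",
]


def build_ppi_subgraph(
    demrnas: set[str],
    ppi: pd.DataFrame,
    min_score: float = 0.700,
) -> nx.Graph:
    """Induce the high-confidence PPI graph on the DE mRNAs.

    ``ppi`` has columns ``gene_a, gene_b, score`` with scores in [0, 1].
    Edges require score >= ``min_score`` (the conventional high-confidence
    setting) and both endpoints differentially expressed; non-interacting
    (isolated) genes are removed.
    """
    if not demrnas:
        raise ValueError("DE mRNA list is empty")
    scores = ppi["score"].astype(float)
    if (scores < 0).any() or (scores > 1).any():
        raise ValueError("PPI scores must lie in [0, 1]")
    keep = (
        (scores >= min_score)
        & ppi["gene_a"].isin(demrnas)
        & ppi["gene_b"].isin(demrnas)
        & (ppi["gene_a"] != ppi["gene_b"])
    )
    g = nx.Graph()
    g.add_edges_from(ppi.loc[keep, ["gene_a", "gene_b"]].itertuples(index=False))
    return g


@dataclass
class HubReport:
    """Degree-ranked genes and the top-k hub selection."""

    ranking: list[tuple[str, int]]  # (gene, degree), degree desc, symbol asc
    hubs: list[str]

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.ranking)


def rank_hubs(graph: nx.Graph, k: int = 5) -> HubReport:
    """Rank nodes by degree (descending), ties broken by symbol, take top k."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot rank hubs of an empty graph")
    ranking = sorted(graph.degree(), key=lambda gd: (-gd[1], gd[0]))
    return HubReport(ranking=ranking, hubs=[g for g, _ in ranking[:k]])


def reconstruct_subnetwork(
    axes_by_tissue: dict[str, list[CeRNAAxis]],
    hub_genes: set[str],
) -> dict:
    """Rebuild per-tissue ceRNA networks restricted to hub-gene axes.

    Keeps exactly the axes whose mRNA is a hub gene and reports the
    distinct lncRNAs/miRNAs/mRNAs across tissues — the "key" transcripts
    the sponge model puts upstream of the hubs.
    """
    sub_axes = {
        t: [a for a in axes if a.mrna in hub_genes]
        for t, axes in axes_by_tissue.items()
    }
    networks = {t: build_network(axes, tissue=t) for t, axes in sub_axes.items()}
    all_axes = [a for axes in sub_axes.values() for a in axes]
    return {
        "axes": sub_axes,
        "networks": networks,
        "key_lncrnas": sorted({a.lncrna for a in all_axes}),
        "key_mirnas": sorted({a.mirna for a in all_axes}),
        "key_mrnas": sorted({a.mrna for a in all_axes}),
    }


def overlap_analysis(lists: dict[str, set[str]]) -> dict:
    """Exhaustive Venn analysis of per-tissue symbol sets.

    Returns the 2^n - 1 exclusive regions (members present in exactly that
    tissue combination), every non-exclusive intersection, the grand union,
    and the brain/blood overlap (union over brain regions of region ∩ LB)
    when an ``LB`` list is present.
    """
    if len(lists) < 2:
        raise ValueError("need at least two lists")
    names = sorted(lists)
    exclusive: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(lists[c] for c in combo))
            outside = set().union(*(lists[n] for n in names if n not in combo), set())
            exclusive[combo] = inside - outside
    intersections = {
        combo: set.intersection(*(lists[c] for c in combo))
        for r in range(2, len(names) + 1)
        for combo in combinations(names, r)
    }
    union = set().union(*lists.values())
    out = {
        "exclusive_regions": exclusive,
        "intersections": intersections,
        "union": union,
    }
    if "LB" in lists:
        brain = [n for n in names if n != "LB"]
        out["brain_blood"] = set().union(
            *(lists[b] & lists["LB"] for b in brain), set()
        )
    return out


def network_summary(graph: nx.Graph) -> dict[str, int]:
    """Type-stratified node counts and edge count of a ceRNA network."""
    counts = {"lncRNA": 0, "miRNA": 0, "mRNA": 0}
    for _, kind in graph.nodes(data="kind"):
        counts[kind] += 1
    return {
        "nodes": graph.number_of_nodes(),
        "lncRNAs": counts["lncRNA"],
        "miRNAs": counts["miRNA"],
        "mRNAs": counts["mRNA"],
        "edges": graph.number_of_edges(),
    }
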