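"""Tissue-specific ceRNA (lncRNA-miRNA-mRNA) axis assembly.

A ceRNA axis is an ordered triple in which a lncRNA is hypothesized to
sponge a miRNA and thereby de-repress an mRNA target of that miRNA. Axes
are assembled by joining three evidence tables — lncRNA-miRNA interactions,
disease-associated miRNAs, and miRNA-mRNA targets — restricted to
differentially expressed lncRNAs/mRNAs, and then pruned to axes whose
lncRNA and mRNA change in the same direction (the sponge model predicts a
positive lncRNA-mRNA expression relationship).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "InteractionCatalog",
    "CeRNAAxis",
    "TISSUE_EVIDENCE_LABELS",
    "filter_catalog",
    "assemble_axes",
    "prune_discordant",
    "build_network",
    "common_axes",
]

# Evidence rows carry the coarse tissue vocabulary of lncRNA-miRNA
# interaction databases; every brain region maps onto the "brain" label.
TISSUE_EVIDENCE_LABELS: dict[str, str] = {
    "HPC": "brain",
    "BA46": "brain",
    "STR": "brain",
    "LB": "peripheral blood",
}

_LNC_MI_COLS = ["lncrna", "mirna", "tissue", "confidence"]
_MI_MRNA_COLS = ["mirna", "mrna", "evidence"]


@dataclass
class InteractionCatalog:
    """Evidence-table snapshot used to assemble ceRNA axes.

    Attributes
    ----------
    lnc_mi
        lncRNA-miRNA interaction records with columns
        ``lncrna, mirna, tissue, confidence`` (confidence in {high, low}).
    disease_mi
        miRNA symbols associated with the disease under study.
    mi_mrna
        miRNA-mRNA target records with columns ``mirna, mrna, evidence``
        (evidence in {strong, weak}).
    """

    lnc_mi: pd.DataFrame
    disease_mi: set[str]
    mi_mrna: pd.DataFrame

    def __post_init__(self) -> None:
        self.lnc_mi = _canonical(self.lnc_mi, _LNC_MI_COLS)
        self.mi_mrna = _canonical(self.mi_mrna, _MI_MRNA_COLS)
        self.disease_mi = set(self.disease_mi)

    @classmethod
    def empty(cls) -> "InteractionCatalog":
        return cls(
            lnc_mi=pd.DataFrame(columns=_LNC_MI_COLS),
            disease_mi=set(),
            mi_mrna=pd.DataFrame(columns=_MI_MRNA_COLS),
        )


def _canonical(table: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"evidence table missing columns {missing}")
    out = table.loc[:, cols].drop_duplicates().reset_index(drop=True)
    if out.isna().any().any() or (out == "").any().any():
        raise ValueError("evidence table contains empty symbols")
    return out


@dataclass(frozen=True)
class CeRNAAxis:
    """One lncRNA-miRNA-mRNA triple with tissue and DE directions."""

    lncrna: str
    mirna: str
    mrna: str
    tissue: str
    lnc_direction: str | None = None
    mrna_direction: str | None = None

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.lncrna, self.mirna, self.mrna)

    @property
    def concordant(self) -> bool:
        if self.lnc_direction is None or self.mrna_direction is None:
            raise ValueError("axis lacks direction annotation")
        return self.lnc_direction == self.mrna_direction


def filter_catalog(
    catalog: InteractionCatalog,
    tissue: str,
    delncs: set[str],
    demrnas: set[str],
    tissue_labels: dict[str, str] | None = None,
) -> InteractionCatalog:
    """Restrict the evidence tables to the study's inclusion criteria.

    Keeps lncRNA-miRNA rows with high confidence, a tissue label matching
    the queried tissue, and a differentially expressed lncRNA; miRNAs in the
    disease-association set; and strongly supported miRNA-mRNA rows whose
    mRNA is differentially expressed.
    """
    labels = tissue_labels if tissue_labels is not None else TISSUE_EVIDENCE_LABELS
    if tissue not in labels:
        raise ValueError(f"unknown tissue {tissue!r}; known: {sorted(labels)}")
    label = labels[tissue]
    lm = catalog.lnc_mi
    lm = lm[
        (lm["confidence"] == "high")
        & (lm["tissue"] == label)
        & lm["lncrna"].isin(delncs)
    ]
    mm = catalog.mi_mrna
    mm = mm[(mm["evidence"] == "strong") & mm["mrna"].isin(demrnas)]
    return InteractionCatalog(
        lnc_mi=lm.reset_index(drop=True),
        disease_mi=set(catalog.disease_mi),
        mi_mrna=mm.reset_index(drop=True),
    )


def assemble_axes(
    catalog: InteractionCatalog,
    tissue: str,
    directions: dict[str, str] | None = None,
) -> list[CeRNAAxis]:
    """Join the filtered tables into every representable (L, M, G) triple.

    Emits each triple such that (L, M) is a lncRNA-miRNA record, M is a
    disease miRNA, and (M, G) is a miRNA-mRNA record; annotates the lncRNA
    and mRNA with their DE directions when ``directions`` is given.
    """
    if catalog.lnc_mi.empty or catalog.mi_mrna.empty or not catalog.disease_mi:
        return []
    lm = catalog.lnc_mi[catalog.lnc_mi["mirna"].isin(catalog.disease_mi)]
    joined = lm.merge(catalog.mi_mrna, on="mirna")
    joined = joined.drop_duplicates(["lncrna", "mirna", "mrna"])
    directions = directions or {}
    return [
        CeRNAAxis(
            lncrna=r.lncrna,
            mirna=r.mirna,
            mrna=r.mrna,
            tissue=tissue,
            lnc_direction=directions.get(r.lncrna),
            mrna_direction=directions.get(r.mrna),
        )
        for r in joined.itertuples(index=False)
    ]


def prune_discordant(axes: list[CeRNAAxis]) -> list[CeRNAAxis]:
    """Drop axes whose lncRNA and mRNA change in opposite directions.

    The sponge model requires a positive lncRNA-mRNA relationship, so only
    same-direction axes are biologically admissible. Nodes participating
    only in discarded axes disappear from any network built afterwards.
    """
    for axis in axes:
        if axis.lnc_direction is None or axis.mrna_direction is None:
            raise ValueError(f"axis {axis.triple} lacks direction annotation")
    return [a for a in axes if a.concordant]


def build_network(axes: list[CeRNAAxis], tissue: str | None = None) -> nx.Graph:
    """Build the tripartite ceRNA graph from (pruned) axes.

    Nodes are typed lncRNA / miRNA / mRNA with a ``direction`` attribute
    where known; edges are the deduplicated union of lncRNA-miRNA and
    miRNA-mRNA pairs. The graph never contains lncRNA-mRNA or same-type
    edges, and no isolated nodes.
    """
    g = nx.Graph()
    g.graph["tissue"] = tissue
    for a in axes:
        g.add_node(a.lncrna, kind="lncRNA", direction=a.lnc_direction or "")
        g.add_node(a.mirna, kind="miRNA", direction="")
        g.add_node(a.mrna, kind="mRNA", direction=a.mrna_direction or "")
        g.add_edge(a.lncrna, a.mirna)
        g.add_edge(a.mirna, a.mrna)
    return g


def common_axes(axes_by_tissue: dict[str, list[CeRNAAxis]]) -> set[tuple[str, str, str]]:
    """Intersect axis triples across tissues (exact symbol-triple identity)."""
    if len(axes_by_tissue) < 2:
        raise ValueError("need at least two tissues to intersect")
    sets = [{a.triple for a in axes} for axes in axes_by_tissue.values()]
    return set.intersection(*sets)
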