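"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is tab-separated UTF-8 with a header row and no quoting; gene
symbols are opaque, case-sensitive strings. Networks export to GraphML
(via networkx) and SIF, both loadable by common network-visualization
tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .cerna import CeRNAAxis, InteractionCatalog
from .enrichment import GeneSetCollection
from .study import ExpressionStudy
from .synthetic import PlantedAxis, TruthTable

__all__ = [
    "write_expression_study",
    "read_expression_study",
    "write_catalog",
    "read_catalog",
    "write_axes",
    "read_axes",
    "write_graphml",
    "read_graphml",
    "write_sif",
    "read_sif",
    "write_gmt",
    "read_gmt",
    "write_truth",
    "read_truth",
    "write_json",
]

_SEP = "\t"


def write_expression_study(study: ExpressionStudy, matrix_path, meta_path) -> None:
    study.matrix.to_csv(matrix_path, sep=_SEP, index_label="gene")
    study.sample_meta.to_csv(meta_path, sep=_SEP, index_label="sample")


def read_expression_study(matrix_path, meta_path, scale: str) -> ExpressionStudy:
    matrix = pd.read_csv(matrix_path, sep=_SEP, index_col="gene")
    meta = pd.read_csv(meta_path, sep=_SEP, index_col="sample")
    matrix.index.name = None
    matrix.columns.name = None
    meta.index.name = None
    return ExpressionStudy(matrix=matrix, scale=scale, sample_meta=meta)


def write_catalog(catalog: InteractionCatalog, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    catalog.lnc_mi.to_csv(directory / "lncrna_mirna.tsv", sep=_SEP, index=False)
    pd.DataFrame({"mirna": sorted(catalog.disease_mi)}).to_csv(
        directory / "disease_mirna.tsv", sep=_SEP, index=False
    )
    catalog.mi_mrna.to_csv(directory / "mirna_mrna.tsv", sep=_SEP, index=False)


def read_catalog(directory) -> InteractionCatalog:
    directory = Path(directory)
    disease = pd.read_csv(directory / "disease_mirna.tsv", sep=_SEP)
    return InteractionCatalog(
        lnc_mi=pd.read_csv(directory / "lncrna_mirna.tsv", sep=_SEP),
        disease_mi=set(disease["mirna"]),
        mi_mrna=pd.read_csv(directory / "mirna_mrna.tsv", sep=_SEP),
    )


def write_axes(axes: list[CeRNAAxis], path) -> None:
    pd.DataFrame(
        [
            (a.lncrna, a.mirna, a.mrna, a.tissue, a.lnc_direction or "",
             a.mrna_direction or "")
            for a in axes
        ],
        columns=["lncrna", "mirna", "mrna", "tissue", "lnc_direction", "mrna_direction"],
    ).to_csv(path, sep=_SEP, index=False)


def read_axes(path) -> list[CeRNAAxis]:
    table = pd.read_csv(path, sep=_SEP, keep_default_na=False)
    return [
        CeRNAAxis(
            lncrna=r.lncrna,
            mirna=r.mirna,
            mrna=r.mrna,
            tissue=r.tissue,
            lnc_direction=r.lnc_direction or None,
            mrna_direction=r.mrna_direction or None,
        )
        for r in table.itertuples(index=False)
    ]


def write_graphml(graph: nx.Graph, path) -> None:
    g = graph.copy()
    if g.graph.get("tissue") is None:
        g.graph.pop("tissue", None)
    nx.write_graphml(g, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_sif(graph: nx.Graph, path) -> None:
    """SIF export: one ``source<TAB>interaction<TAB>target`` line per edge.

    The interaction keyword encodes the edge kind (``lnc-mi`` or
    ``mi-mrna``) inferred from node types; untyped graphs use ``pp``.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(graph.edges()):
            ka = graph.nodes[a].get("kind")
            kb = graph.nodes[b].get("kind")
            kinds = {ka, kb}
            if kinds == {"lncRNA", "miRNA"}:
                rel = "lnc-mi"
            elif kinds == {"miRNA", "mRNA"}:
                rel = "mi-mrna"
            else:
                rel = "pp"
            fh.write(f"{a}{_SEP}{rel}{_SEP}{b}\n")


def read_sif(path) -> nx.Graph:
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split(_SEP)
            if len(parts) != 3:
                raise ValueError(f"malformed SIF line: {line!r}")
            a, rel, b = parts
            g.add_edge(a, b, interaction=rel)
    return g


def write_gmt(collection: GeneSetCollection, path, description: str = "synthetic") -> None:
    """GMT: one set per line — name, description, tab-separated members."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            fh.write(_SEP.join([name, description, *sorted(members)]) + "\n")


def read_gmt(path, universe: set[str] | None = None) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    members_all: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            fields = line.rstrip("\n").split(_SEP)
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            name, _desc, *members = fields
            sets[name] = set(members)
            members_all |= sets[name]
    return GeneSetCollection(sets=sets, universe=universe or members_all)


def write_truth(truth: TruthTable, path) -> None:
    payload = {
        "de_genes": truth.de_genes,
        "planted_axes": [
            {"lncrna": a.lncrna, "mirna": a.mirna, "mrna": a.mrna,
             "tissue": a.tissue, "concordant": a.concordant}
            for a in truth.planted_axes
        ],
        "outlier_sample": truth.outlier_sample,
        "lncrna_catalog": sorted(truth.lncrna_catalog),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> TruthTable:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return TruthTable(
        de_genes={t: dict(g) for t, g in payload["de_genes"].items()},
        planted_axes=[PlantedAxis(**a) for a in payload["planted_axes"]],
        outlier_sample=payload["outlier_sample"],
        lncrna_catalog=set(payload["lncrna_catalog"]),
    )


def write_json(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, set):
        return sorted(obj)
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
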