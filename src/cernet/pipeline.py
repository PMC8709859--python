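"""End-to-end orchestration: simulate -> preprocess -> DE -> ceRNA -> hubs
-> enrichment, with every stage's outputs written under a run directory.

The default run generates the two synthetic studies the package emulates
(a three-region brain study and a lymphoblast study), preprocesses each
separately, calls differential expression per tissue with the study's
covariates, assembles and prunes tissue-specific ceRNA axes from a
generated evidence catalog, ranks PPI hub genes, reconstructs the hub
subnetwork, runs gene-set enrichment of the ceRNA mRNAs, and compares
recovered axes against the planted truth. Identical config (including
seed) produces byte-identical text outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import cerna, diffexpr, enrichment, io, network, preprocess, synthetic
from .study import ExpressionStudy
from .synthetic import StudyConfig, TruthTable

__all__ = ["PipelineConfig", "run_pipeline", "preprocess_study", "recovered_vs_planted"]

log = logging.getLogger("cernet")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; serialized into the run directory."""

    out_dir: str = "results/run"
    seed: int = 0
    # generator settings (study structure comes from the default configs)
    frac_de: float = 0.05
    de_log2fc: float = 2.0
    noise_sd: float = 0.5
    n_genes: int = 2000
    n_lncrnas: int = 100
    n_decoys: int = 50
    outlier: tuple[str, str, float] | None = None
    # preprocessing
    min_signal: float = 100.0
    min_frac: float = 0.25
    flag_outlier_k: float = 5.0
    # differential expression
    adjp_max: float = 0.001
    min_abs_log2fc: float = 0.69
    moderated: bool = True
    # downstream
    ppi_min_score: float = 0.700
    hub_k: int = 5
    n_gene_sets: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("outlier") is not None:
            raw["outlier"] = tuple(raw["outlier"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        if raw["outlier"] is not None:
            raw["outlier"] = list(raw["outlier"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class PreprocessResult:
    study: ExpressionStudy  # log2, filtered, outliers removed
    qc: preprocess.QCReport
    kept_genes: list[str]
    dropped_samples: list[str]
    batch_adjusted: ExpressionStudy | None = None


def filter_genes(
    study: ExpressionStudy, min_signal: float = 100.0, min_frac: float = 0.25
) -> ExpressionStudy:
    """Intensity filter on linear values, then IQR filter on log2 values.

    Applied to the sample set over which differential expression will be
    tested, so that region-restricted signal is judged against that
    region's own variability.
    """
    expressed = preprocess.intensity_filter(study.to_linear(), min_signal, min_frac)
    log2 = study.to_linear().subset_genes(expressed).to_log2()
    variable = preprocess.iqr_filter(log2)
    return log2.subset_genes(variable)


def preprocess_study(
    raw: ExpressionStudy,
    min_signal: float = 100.0,
    min_frac: float = 0.25,
    flag_k: float = 5.0,
) -> PreprocessResult:
    """Normalize, filter, QC-flag, and batch-adjust one study.

    Quantile normalization on the linear scale; the intensity filter on the
    normalized linear values; the IQR filter on the log2 values; sample
    flags from the PC-distance rule, with flagged samples removed; the
    batch-adjusted matrix is produced for visualization only.
    """
    normed = preprocess.quantile_normalize(raw.to_linear())
    expressed = preprocess.intensity_filter(normed, min_signal, min_frac)
    log2 = normed.subset_genes(expressed).to_log2()
    variable = preprocess.iqr_filter(log2)
    filtered = log2.subset_genes(variable)
    qc = preprocess.qc_report(filtered, flag_k=flag_k)
    dropped = preprocess.flag_outliers(qc)
    clean = filtered.drop_samples(dropped) if dropped else filtered
    adjusted = None
    if "batch" in clean.sample_meta.columns and clean.sample_meta["batch"].nunique() > 1:
        adjusted = preprocess.remove_batch_effect(clean)
    return PreprocessResult(
        study=clean,
        qc=qc,
        kept_genes=list(clean.matrix.index),
        dropped_samples=dropped,
        batch_adjusted=adjusted,
    )


def _study_configs(cfg: PipelineConfig) -> dict[str, StudyConfig]:
    shared = dict(
        n_genes=cfg.n_genes,
        n_lncrnas=cfg.n_lncrnas,
        frac_de=cfg.frac_de,
        de_log2fc=cfg.de_log2fc,
        noise_sd=cfg.noise_sd,
    )
    brain_extra = {}
    blood_extra = {}
    if cfg.outlier is not None:
        target = {"brain": brain_extra, "blood": blood_extra}[
            "blood" if cfg.outlier[0] == "LB" else "brain"
        ]
        target["outlier"] = cfg.outlier
    return {
        "brain": synthetic.brain_study_config(seed=cfg.seed, **shared, **brain_extra),
        "blood": synthetic.blood_study_config(seed=cfg.seed + 1, **shared, **blood_extra),
    }


_COVARIATES = {"brain": ("race", "pmi"), "blood": ("age", "sex", "race")}


def _merge_truths(truths: dict[str, TruthTable]) -> TruthTable:
    merged = TruthTable(de_genes={}, planted_axes=[], lncrna_catalog=set())
    for t in truths.values():
        merged.de_genes.update(t.de_genes)
        merged.planted_axes.extend(t.planted_axes)
        merged.lncrna_catalog |= t.lncrna_catalog
        if t.outlier_sample:
            merged.outlier_sample = t.outlier_sample
    return merged


def recovered_vs_planted(
    recovered: dict[str, list[cerna.CeRNAAxis]], truth: TruthTable
) -> dict[str, float]:
    """Precision/recall of recovered axes against planted concordant axes."""
    got = {(a.lncrna, a.mirna, a.mrna, a.tissue) for axes in recovered.values() for a in axes}
    want = {(a.lncrna, a.mirna, a.mrna, a.tissue) for a in truth.concordant_axes()}
    tp = len(got & want)
    return {
        "true_positives": tp,
        "recovered": len(got),
        "planted": len(want),
        "precision": tp / len(got) if got else 1.0,
        "recall": tp / len(want) if want else 1.0,
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write its artifacts under ``cfg.out_dir``.

    Returns an in-memory results dictionary (studies, DE tables, axes,
    networks, hub report, overlap regions, enrichment table, recovery
    metrics) mirroring the files written.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    logging.basicConfig(level=logging.INFO, format="%(message)s")

    # --- stage 1: simulate ---
    configs = _study_configs(cfg)
    studies: dict[str, ExpressionStudy] = {}
    truths: dict[str, TruthTable] = {}
    for name, sc in configs.items():
        study, truth = synthetic.gen_expression_study(sc)
        studies[name], truths[name] = study, truth
        io.write_expression_study(
            study, out / f"{name}_expression.tsv", out / f"{name}_samples.tsv"
        )
        log.info("simulate[%s]: %d genes x %d samples, %d planted axes",
                 name, study.n_genes, study.n_samples, len(truth.planted_axes))
    truth = _merge_truths(truths)
    io.write_truth(truth, out / "truth.json")
    catalog = synthetic.gen_interaction_catalog(
        truth, n_decoys=cfg.n_decoys, seed=cfg.seed + 2
    )
    io.write_catalog(catalog, out / "catalog")

    # --- stage 2: normalize and QC (each study separately) ---
    prep: dict[str, PreprocessResult] = {}
    for name, study in studies.items():
        normed = preprocess.quantile_normalize(study.to_linear())
        qc = preprocess.qc_report(normed.to_log2(), flag_k=cfg.flag_outlier_k)
        dropped = preprocess.flag_outliers(qc)
        clean = normed.drop_samples(dropped) if dropped else normed
        adjusted = None
        if clean.sample_meta["batch"].nunique() > 1:
            adjusted = preprocess.remove_batch_effect(clean)
        prep[name] = PreprocessResult(
            study=clean, qc=qc, kept_genes=[], dropped_samples=dropped,
            batch_adjusted=adjusted,
        )
        io.write_json(qc.to_dict(), out / f"{name}_qc.json")
        log.info("preprocess[%s]: %d samples retained, dropped: %s",
                 name, clean.n_samples, dropped or "none")

    # --- stage 3: per-tissue gene filtering and differential expression ---
    de_tables: dict[str, pd.DataFrame] = {}
    for name, res in prep.items():
        kept: set[str] = set()
        for tissue in res.study.sample_meta["tissue"].unique():
            sub = res.study.subset_samples(
                res.study.sample_meta.index[res.study.sample_meta["tissue"] == tissue]
            )
            filtered = filter_genes(sub, cfg.min_signal, cfg.min_frac)
            kept |= set(filtered.matrix.index)
            log.info("filter[%s]: %d/%d genes retained",
                     tissue, filtered.n_genes, sub.n_genes)
            table = diffexpr.differential_expression(
                filtered,
                covariates=_COVARIATES[name],
                lncrna_catalog=truth.lncrna_catalog,
                adjp_max=cfg.adjp_max,
                min_abs_log2fc=cfg.min_abs_log2fc,
                moderated=cfg.moderated,
            )
            table["tissue"] = tissue
            de_tables[tissue] = table
            de = table[table["direction"] != "ns"]
            log.info("de[%s]: %d DEmRNAs (%d up, %d down), %d DElncRNAs",
                     tissue,
                     (de["gene_class"] == "mRNA").sum(),
                     ((de["gene_class"] == "mRNA") & (de["direction"] == "up")).sum(),
                     ((de["gene_class"] == "mRNA") & (de["direction"] == "down")).sum(),
                     (de["gene_class"] == "lncRNA").sum())
            table.to_csv(out / f"de_{tissue}.tsv", sep="\t", index_label="gene")
        res.kept_genes = sorted(kept)

    # --- stage 4: ceRNA assembly per tissue ---
    axes_by_tissue: dict[str, list[cerna.CeRNAAxis]] = {}
    networks = {}
    for tissue, table in de_tables.items():
        de = table[table["direction"] != "ns"]
        delncs = set(de.index[de["gene_class"] == "lncRNA"])
        demrnas = set(de.index[de["gene_class"] == "mRNA"])
        directions = de["direction"].to_dict()
        filt = cerna.filter_catalog(catalog, tissue, delncs, demrnas)
        axes = cerna.assemble_axes(filt, tissue, directions)
        axes = cerna.prune_discordant(axes)
        axes_by_tissue[tissue] = axes
        net = cerna.build_network(axes, tissue)
        networks[tissue] = net
        io.write_axes(axes, out / f"axes_{tissue}.tsv")
        io.write_graphml(net, out / f"cerna_{tissue}.graphml")
        io.write_sif(net, out / f"cerna_{tissue}.sif")
        summary = network.network_summary(net)
        log.info("cerna[%s]: %d axes; %d nodes, %d edges",
                 tissue, len(axes), summary["nodes"], summary["edges"])

    brain_tissues = [t for t in axes_by_tissue if t != "LB"]
    common = (
        cerna.common_axes({t: axes_by_tissue[t] for t in brain_tissues})
        if len(brain_tissues) >= 2
        else set()
    )

    # --- stage 5: PPI, hubs, subnetwork ---
    hub_reports: dict[str, network.HubReport] = {}
    ppi_tables: dict[str, pd.DataFrame] = {}
    for i, tissue in enumerate(sorted(axes_by_tissue)):
        net_mrnas = sorted({a.mrna for a in axes_by_tissue[tissue]})
        de = de_tables[tissue]
        demrnas = set(de.index[(de["direction"] != "ns") & (de["gene_class"] == "mRNA")])
        if not net_mrnas or len(demrnas) < 2:
            continue
        planned = net_mrnas[: cfg.hub_k]
        max_deg = min(len(demrnas) - 1, cfg.hub_k + 7)
        hub_plan = {g: max_deg - j for j, g in enumerate(planned) if max_deg - j >= 1}
        ppi = synthetic.gen_ppi_table(
            sorted(demrnas), hub_plan, seed=cfg.seed + 10 + i
        )
        ppi_tables[tissue] = ppi
        ppi.to_csv(out / f"ppi_{tissue}.tsv", sep="\t", index=False)
        graph = network.build_ppi_subgraph(demrnas, ppi, min_score=cfg.ppi_min_score)
        if graph.number_of_nodes() == 0:
            continue
        hub_reports[tissue] = network.rank_hubs(graph, k=cfg.hub_k)
        log.info("hubs[%s]: %s", tissue, hub_reports[tissue].hubs)
    hub_union = sorted({h for r in hub_reports.values() for h in r.hubs})
    subnet = network.reconstruct_subnetwork(axes_by_tissue, set(hub_union))
    pd.DataFrame(
        [(t, g, d) for t, r in hub_reports.items() for g, d in r.ranking],
        columns=["tissue", "gene", "degree"],
    ).to_csv(out / "hub_report.tsv", sep="\t", index=False)
    for tissue, net in subnet["networks"].items():
        io.write_graphml(net, out / f"subcerna_{tissue}.graphml")
        io.write_sif(net, out / f"subcerna_{tissue}.sif")

    # --- stage 6: overlap analysis (Venn) ---
    deg_sets = {
        t: set(tab.index[tab["direction"] != "ns"]) for t, tab in de_tables.items()
    }
    venn = network.overlap_analysis(deg_sets) if len(deg_sets) >= 2 else None
    if venn is not None:
        io.write_json(
            {
                "exclusive_regions": {
                    "&".join(k): sorted(v) for k, v in venn["exclusive_regions"].items()
                },
                "union": sorted(venn["union"]),
                "brain_blood": sorted(venn.get("brain_blood", set())),
            },
            out / "venn.json",
        )

    # --- stage 7: enrichment of ceRNA-network mRNAs ---
    enrich_table = None
    all_net_mrnas = sorted({a.mrna for axes in axes_by_tissue.values() for a in axes})
    universe = sorted(set().union(*(set(r.kept_genes) for r in prep.values())))
    if all_net_mrnas:
        collection = synthetic.gen_gene_sets(
            universe, cfg.n_gene_sets, set(all_net_mrnas), seed=cfg.seed + 20
        )
        io.write_gmt(collection, out / "gene_sets.gmt")
        enrich_table = enrichment.fisher_enrich(set(all_net_mrnas), collection)
        enrich_table.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    recovery = recovered_vs_planted(axes_by_tissue, truth)
    io.write_json(
        {
            "recovery": recovery,
            "common_brain_axes": sorted(common),
            "hub_union": hub_union,
            "key_lncrnas": subnet["key_lncrnas"],
            "key_mirnas": subnet["key_mirnas"],
            "key_mrnas": subnet["key_mrnas"],
        },
        out / "summary.json",
    )
    log.info("recovery: precision=%.3f recall=%.3f (%d planted)",
             recovery["precision"], recovery["recall"], recovery["planted"])

    return {
        "config": cfg,
        "studies": studies,
        "truth": truth,
        "catalog": catalog,
        "preprocess": prep,
        "de_tables": de_tables,
        "axes_by_tissue": axes_by_tissue,
        "networks": networks,
        "common_brain_axes": common,
        "ppi_tables": ppi_tables,
        "hub_reports": hub_reports,
        "hub_union": hub_union,
        "subnetwork": subnet,
        "venn": venn,
        "enrichment": enrich_table,
        "recovery": recovery,
    }
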