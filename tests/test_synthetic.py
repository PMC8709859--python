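"""Generator structure, determinism, planted effects, and evidence tables."""

import numpy as np
import pandas as pd
import pytest

from cernet import cerna, enrichment, network
from cernet.synthetic import (
    StudyConfig,
    blood_study_config,
    brain_study_config,
    gen_expression_study,
    gen_gene_sets,
    gen_interaction_catalog,
    gen_ppi_table,
)


class TestExpressionStudy:
    def test_brain_study_group_structure(self):
        study, _ = gen_expression_study(
            brain_study_config(seed=0, n_genes=50, n_lncrnas=10)
        )
        meta = study.sample_meta
        cases = meta[meta["condition"] == "case"]
        controls = meta[meta["condition"] == "control"]
        assert len(cases) == 48
        assert cases["tissue"].value_counts().to_dict() == {"STR": 18, "HPC": 15, "BA46": 15}
        assert len(controls) == 55
        assert controls["tissue"].value_counts().to_dict() == {"BA46": 19, "HPC": 18, "STR": 18}

    def test_blood_study_has_thirty_samples(self):
        study, _ = gen_expression_study(
            blood_study_config(seed=0, n_genes=50, n_lncrnas=10)
        )
        assert study.n_samples == 30
        assert (study.sample_meta["condition"] == "case").sum() == 15

    def test_matrix_linear_positive_and_metadata_aligned(self):
        study, _ = gen_expression_study(blood_study_config(seed=1, n_genes=40, n_lncrnas=5))
        assert study.scale == "linear"
        assert (study.matrix.to_numpy() > 0).all()
        assert list(study.matrix.columns) == list(study.sample_meta.index)
        for col in ("tissue", "condition", "batch", "age", "sex", "race"):
            assert col in study.sample_meta.columns

    def test_no_de_means_empty_truth(self):
        _, truth = gen_expression_study(
            blood_study_config(seed=2, n_genes=50, n_lncrnas=10, frac_de=0.0)
        )
        assert all(not genes for genes in truth.de_genes.values())
        assert truth.planted_axes == []

    def test_planted_effects_recovered_within_4se(self):
        # covariate-free so the group-mean contrast is the planted effect
        cfg = StudyConfig(
            groups_per_tissue={"LB": (15, 15)},
            n_genes=1000,
            n_lncrnas=100,
            frac_de=0.2,
            de_log2fc=2.0,
            noise_sd=0.5,
            seed=11,
        )
        study, truth = gen_expression_study(cfg)
        log2 = study.to_log2()
        meta = log2.sample_meta
        case_ids = meta.index[meta["condition"] == "case"]
        ctrl_ids = meta.index[meta["condition"] == "control"]
        effects = truth.de_genes["LB"]
        assert len(effects) >= 200
        for gene, eff in effects.items():
            case = log2.matrix.loc[gene, case_ids]
            ctrl = log2.matrix.loc[gene, ctrl_ids]
            diff = case.mean() - ctrl.mean()
            se = np.sqrt(case.var(ddof=1) / len(case) + ctrl.var(ddof=1) / len(ctrl))
            assert abs(diff - eff) < 4 * se

    def test_same_seed_reproduces_everything(self):
        cfg = brain_study_config(seed=5, n_genes=60, n_lncrnas=10)
        s1, t1 = gen_expression_study(cfg)
        s2, t2 = gen_expression_study(cfg)
        pd.testing.assert_frame_equal(s1.matrix, s2.matrix)
        pd.testing.assert_frame_equal(s1.sample_meta, s2.sample_meta)
        assert t1.planted_axes == t2.planted_axes
        assert t1.de_genes == t2.de_genes

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            StudyConfig(groups_per_tissue={"LB": (0, 15)})
        with pytest.raises(ValueError):
            StudyConfig(groups_per_tissue={"LB": (5, 5)}, frac_de=1.5)
        with pytest.raises(ValueError):
            StudyConfig(groups_per_tissue={"LB": (5, 5)}, noise_sd=0.0)

    def test_planted_axis_members_are_de(self):
        _, truth = gen_expression_study(
            brain_study_config(seed=7, n_genes=300, n_lncrnas=40, frac_de=0.1)
        )
        assert truth.planted_axes
        for axis in truth.planted_axes:
            assert axis.lncrna in truth.de_genes[axis.tissue]
            assert axis.mrna in truth.de_genes[axis.tissue]
            same_sign = np.sign(truth.de_genes[axis.tissue][axis.lncrna]) == np.sign(
                truth.de_genes[axis.tissue][axis.mrna]
            )
            assert axis.concordant == same_sign


class TestInteractionCatalog:
    def test_empty_truth_gives_empty_tables(self):
        _, truth = gen_expression_study(
            blood_study_config(seed=0, n_genes=30, n_lncrnas=5, frac_de=0.0)
        )
        catalog = gen_interaction_catalog(truth, n_decoys=0, seed=0)
        assert catalog.lnc_mi.empty
        assert catalog.mi_mrna.empty
        assert catalog.disease_mi == set()

    def test_planted_axes_fully_representable(self):
        _, truth = gen_expression_study(
            brain_study_config(seed=3, n_genes=400, n_lncrnas=40, frac_de=0.1)
        )
        catalog = gen_interaction_catalog(truth, n_decoys=40, seed=1)
        lm = catalog.lnc_mi.set_index(["lncrna", "mirna"])
        mm = catalog.mi_mrna.set_index(["mirna", "mrna"])
        for a in truth.planted_axes:
            row = lm.loc[(a.lncrna, a.mirna)]
            assert row["confidence"] == "high"
            assert row["tissue"] == cerna.TISSUE_EVIDENCE_LABELS[a.tissue]
            assert a.mirna in catalog.disease_mi
            assert mm.loc[(a.mirna, a.mrna), "evidence"] == "strong"

    def test_assembly_on_truth_recovers_exactly_planted_concordant(self):
        _, truth = gen_expression_study(
            brain_study_config(seed=9, n_genes=500, n_lncrnas=50, frac_de=0.1)
        )
        concordant = truth.concordant_axes()
        assert len(concordant) >= 10
        catalog = gen_interaction_catalog(truth, n_decoys=60, seed=2)
        recovered = set()
        for tissue, effects in truth.de_genes.items():
            directions = {g: ("up" if e > 0 else "down") for g, e in effects.items()}
            delncs = {g for g in effects if g.startswith("LNC")}
            demrnas = {g for g in effects if g.startswith("GENE")}
            filt = cerna.filter_catalog(catalog, tissue, delncs, demrnas)
            axes = cerna.prune_discordant(cerna.assemble_axes(filt, tissue, directions))
            recovered |= {(a.lncrna, a.mirna, a.mrna, a.tissue) for a in axes}
        planted = {(a.lncrna, a.mirna, a.mrna, a.tissue) for a in concordant}
        assert recovered == planted  # precision = recall = 1.0

    def test_only_discordant_axes_yield_empty_network(self):
        _, truth = gen_expression_study(
            brain_study_config(seed=9, n_genes=500, n_lncrnas=50, frac_de=0.1)
        )
        truth.planted_axes = [a for a in truth.planted_axes if not a.concordant]
        assert truth.planted_axes
        catalog = gen_interaction_catalog(truth, n_decoys=0, seed=3)
        for tissue, effects in truth.de_genes.items():
            directions = {g: ("up" if e > 0 else "down") for g, e in effects.items()}
            filt = cerna.filter_catalog(
                catalog, tissue,
                {g for g in effects if g.startswith("LNC")},
                {g for g in effects if g.startswith("GENE")},
            )
            axes = cerna.prune_discordant(cerna.assemble_axes(filt, tissue, directions))
            assert cerna.build_network(axes, tissue).number_of_nodes() == 0


class TestPPIAndGeneSets:
    def test_hub_degrees_realized_exactly(self):
        genes = [f"G{i}" for i in range(10)]
        table = gen_ppi_table(genes, {"G1": 5}, seed=0)
        high = table[table["score"] >= 0.700]
        assert ((high["gene_a"] == "G1") | (high["gene_b"] == "G1")).sum() == 5
        assert (table["score"] >= 0).all() and (table["score"] <= 1).all()

    def test_empty_plan_has_no_high_confidence_edges(self):
        table = gen_ppi_table([f"G{i}" for i in range(12)], {}, seed=1)
        assert (table["score"] < 0.700).all()

    def test_excessive_degree_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            gen_ppi_table([f"G{i}" for i in range(5)], {"G0": 5}, seed=0)

    def test_planted_set_ranks_first_in_enrichment(self):
        genes = [f"G{i}" for i in range(200)]
        planted = set(genes[:10])
        collection = gen_gene_sets(genes, n_sets=10, planted_set=planted, seed=4)
        table = enrichment.fisher_enrich(planted, collection)
        assert table.iloc[0]["term"] == "planted_pathway"
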