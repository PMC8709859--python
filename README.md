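# cernet

**lncRNA-associated competing-endogenous-RNA (ceRNA) network inference for
case/control expression studies.**

Schizophrenia transcriptomics motivates this package: postmortem brain
regions (hippocampus, Brodmann area 46, striatum) and peripheral-blood
lymphoblasts of patients and controls are profiled on expression arrays,
and the question is which long non-coding RNAs (lncRNAs) may act as miRNA
*sponges* — transcripts that soak up a shared miRNA pool and thereby
de-repress that miRNA's mRNA targets. `cernet` implements the complete
desk-scale analysis:

1. **Preprocessing** — quantile normalization, intensity filter
   (signal > 100 in ≥ 25 % of arrays), IQR filter (gene IQR above the
   median gene IQR on the log2 scale), correlation/PCA sample QC with an
   automated outlier flag, and batch-effect removal that protects the
   condition contrast.
2. **Differential expression** — per-gene linear models on condition plus
   covariates, empirical-Bayes moderated *t* statistics
   (s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), with (d₀, s₀²) moment-estimated
   from log s²_g), Benjamini–Hochberg FDR, and DE calls at
   adjP < 0.001 and |log2FC| > 0.69, partitioned into mRNA/lncRNA classes
   by an HGNC-style lncRNA symbol catalog.
3. **ceRNA assembly** — joins three local evidence tables (high-confidence
   tissue-matched lncRNA–miRNA interactions, disease-associated miRNAs,
   strong-evidence miRNA–mRNA targets) into lncRNA–miRNA–mRNA axes, and
   prunes axes whose lncRNA and mRNA change in opposite directions, since
   the sponge model predicts a *positive* lncRNA–mRNA relationship.
4. **Network analysis** — PPI subgraphs at the 0.700 high-confidence
   score, degree-ranked hub genes (top 5 per tissue), hub-restricted
   sub-ceRNA networks, cross-tissue axis intersections, and Venn overlap
   of DEG lists.
5. **Enrichment** — one-sided Fisher exact (hypergeometric tail)
   over-representation of network mRNAs against a local GMT collection.

Because the original array data live in GEO, everything here runs on two
substitutes: **bundled fixtures** transcribed from the study's printed
result tables (the ceRNA axis table, the brain/blood overlap table, the
per-region hub lists), and a **synthetic-data generator** that emulates
the two cohorts (48 patient brain samples split 15/15/18 across three
regions vs 55 controls; 15 vs 15 lymphoblasts) with planted DE genes,
planted concordant/discordant axes, covariate/batch structure and an
optional outlier sample — with the planted truth returned for recovery
testing.

## Worked example

The analysis is organised as numbered drivers under `analysis/`:

```bash
python analysis/01_simulate_studies.py --seed 1
python analysis/02_preprocess_qc.py
python analysis/03_differential_expression.py
python analysis/04_cerna_networks.py
python analysis/05_hubs_and_overlap.py --seed 1
python analysis/06_enrichment.py --seed 1
python analysis/07_published_table_counts.py
```

Selected output from a seed-1 run (abridged):

```
brain: 2100 genes x 103 samples (48 cases), 3 tissue(s), 315 planted DE genes, 30 planted axes (12 concordant)
brain: median intensity 519.4 on every array; two-cluster cut sizes [15, 88]; flagged: none
HPC: 920/2100 genes tested (d0=inf); 101 DEmRNAs (70 up, 31 down), 5 DElncRNAs
HPC: 10 assembled, 7 discordant pruned -> 9 nodes (3 lncRNA, 3 miRNA, 3 mRNA), 6 edges
recovery vs planted truth: precision 1.000, recall 1.000 (18 planted concordant axes)
  * planted_pathway: k=18/18, p=1.19e-43, adjP=2.38e-42
```

Reading this: the generator planted 315 DE genes and 30 axes in the brain
study; after normalization no sample was flagged; per tissue roughly half
the genes pass the non-specific filters and the planted effects are called
DE; assembly plus direction-concordance pruning recovers **exactly** the
planted concordant axes (precision = recall = 1.0) while every discordant
axis is removed; and the positive-control gene set containing the network
mRNAs ranks first in the Fisher enrichment.

Script 07 re-derives the published countable results from the bundled
tables: the single lymphoblast axis (MALAT1 / hsa-miR-9-5p / STARD13)
gives a 3-node, 2-edge network; 90 axis triples are shared by all three
brain regions; the three per-region top-5 hub lists union to 11 genes;
restricting the axis table to those hubs leaves 9 key lncRNAs and 17 key
miRNAs; and 15 DEmRNAs overlap between brain and blood, 7 of them
(ADM, F13A1 and five HLA class-II genes) in all four tissues.

The same stages are available as one call:

```python
from cernet.pipeline import PipelineConfig, run_pipeline
res = run_pipeline(PipelineConfig(out_dir="results/run", seed=1))
res["recovery"]          # {'precision': 1.0, 'recall': 1.0, ...}
```

## Layout

```
src/cernet/        library: study.py, synthetic.py, preprocess.py,
                   diffexpr.py, cerna.py, network.py, enrichment.py,
                   fixtures.py, io.py, pipeline.py
analysis/          numbered narrative drivers (see above)
scripts/           acceptance.py
tests/             pytest suite (unit, property, end-to-end)
docs/methods.md    model, assumptions, parameter choices, limitations
```
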