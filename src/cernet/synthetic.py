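"""Synthetic expression studies and evidence tables with planted ground truth.

The generator emulates the structure of two-channel-free microarray
case/control studies of the kind the pipeline targets: a three-region
postmortem brain study (48 patient samples split 15/15/18 across
hippocampus, Brodmann area 46 and striatum versus 55 controls split
18/19/18) and a peripheral-blood lymphoblast study (15 versus 15). Log2
expression is a per-gene baseline plus additive condition, covariate and
batch effects plus Gaussian noise; the exported matrix is linear-scale
(2^x) so intensity filtering is meaningful. Every planted feature (DE
genes, ceRNA axes, outlier sample) is recorded in a TruthTable, the oracle
for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cerna import TISSUE_EVIDENCE_LABELS, InteractionCatalog
from .enrichment import GeneSetCollection
from .study import ExpressionStudy

__all__ = [
    "CovariateSpec",
    "StudyConfig",
    "PlantedAxis",
    "TruthTable",
    "brain_study_config",
    "blood_study_config",
    "gen_expression_study",
    "gen_interaction_catalog",
    "gen_ppi_table",
    "gen_gene_sets",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One nuisance covariate: numeric (standardized slope) or categorical
    (two balanced levels with an additive offset for the second level)."""

    name: str
    kind: str  # "numeric" | "categorical"
    effect: float  # additive log2-scale effect size

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "categorical"):
            raise ValueError(f"covariate kind must be numeric|categorical, got {self.kind!r}")


@dataclass
class StudyConfig:
    """Generator settings for one synthetic expression study."""

    groups_per_tissue: dict[str, tuple[int, int]]  # tissue -> (n_case, n_control)
    n_genes: int = 2000
    n_lncrnas: int = 100
    frac_de: float = 0.05
    de_log2fc: float = 2.0
    noise_sd: float = 0.5
    covariates: tuple[CovariateSpec, ...] = ()
    n_batches: int = 1
    batch_shift: float = 0.0
    outlier: tuple[str, str, float] | None = None  # (tissue, condition, shift_sd)
    frac_de_down: float = 0.3  # planted down-regulated fraction
    axes_per_lncrna: int = 2
    mirna_offset: int = 0  # namespaces miRNA ids across co-analyzed studies
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups_per_tissue:
            raise ValueError("need at least one tissue")
        for t, (nc, nk) in self.groups_per_tissue.items():
            if nc <= 0 or nk <= 0:
                raise ValueError(f"non-positive group size for tissue {t}")
        if self.n_genes <= 0 or self.n_lncrnas <= 0 or self.n_batches <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ValueError("frac_de must lie in [0, 1]")
        if self.noise_sd <= 0 or self.de_log2fc <= 0:
            raise ValueError("noise_sd and de_log2fc must be positive")


@dataclass(frozen=True)
class PlantedAxis:
    lncrna: str
    mirna: str
    mrna: str
    tissue: str
    concordant: bool

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.lncrna, self.mirna, self.mrna)


@dataclass
class TruthTable:
    """Ground truth emitted alongside a synthetic study."""

    de_genes: dict[str, dict[str, float]]  # tissue -> gene -> signed log2FC
    planted_axes: list[PlantedAxis] = field(default_factory=list)
    outlier_sample: str | None = None
    lncrna_catalog: set[str] = field(default_factory=set)

    def concordant_axes(self) -> list[PlantedAxis]:
        return [a for a in self.planted_axes if a.concordant]


def brain_study_config(seed: int = 0, **overrides) -> StudyConfig:
    """Default three-region brain study: 48 cases vs 55 controls, race and
    post-mortem-interval covariates, two scanner batches."""
    kwargs = dict(
        groups_per_tissue={"HPC": (15, 18), "BA46": (15, 19), "STR": (18, 18)},
        covariates=(
            CovariateSpec("race", "categorical", 0.2),
            CovariateSpec("pmi", "numeric", 0.1),
        ),
        n_batches=2,
        batch_shift=0.4,
        seed=seed,
    )
    kwargs.update(overrides)
    return StudyConfig(**kwargs)


def blood_study_config(seed: int = 0, **overrides) -> StudyConfig:
    """Default lymphoblast study: 15 cases vs 15 controls, age/sex/race
    covariates, single batch."""
    kwargs = dict(
        groups_per_tissue={"LB": (15, 15)},
        covariates=(
            CovariateSpec("age", "numeric", 0.1),
            CovariateSpec("sex", "categorical", 0.2),
            CovariateSpec("race", "categorical", 0.2),
        ),
        mirna_offset=5000,
        seed=seed,
    )
    kwargs.update(overrides)
    return StudyConfig(**kwargs)


def _gene_ids(config: StudyConfig) -> tuple[list[str], list[str]]:
    mrnas = [f"GENE{i:05d}" for i in range(1, config.n_genes + 1)]
    lncs = [f"LNC{i:04d}" for i in range(1, config.n_lncrnas + 1)]
    return mrnas, lncs


def gen_expression_study(config: StudyConfig) -> tuple[ExpressionStudy, TruthTable]:
    """Generate a linear-scale expression study plus its TruthTable.

    Per-tissue DE genes (a ``frac_de`` fraction of mRNAs and of lncRNAs)
    are shifted by ±``de_log2fc`` in cases on the log2 scale; planted genes
    have baselines in [8, 11] log2 so their signal survives intensity
    filtering in both directions. Planted ceRNA axes pair each planted DE
    lncRNA with planted DE mRNAs of the same tissue through a dedicated
    miRNA; the concordance flag records whether their planted directions
    match. Identical config (including seed) reproduces identical output.
    """
    rng = np.random.default_rng(config.seed)
    mrnas, lncs = _gene_ids(config)
    all_genes = mrnas + lncs
    n_total = len(all_genes)
    baseline = rng.uniform(5.0, 12.0, n_total)
    gene_pos = {g: i for i, g in enumerate(all_genes)}

    # plant per-tissue DE genes
    de_genes: dict[str, dict[str, float]] = {}
    planted_axes: list[PlantedAxis] = []
    mirna_counter = config.mirna_offset + 1
    for tissue in config.groups_per_tissue:
        n_de_m = int(round(config.frac_de * config.n_genes))
        n_de_l = int(round(config.frac_de * config.n_lncrnas))
        de_m = [str(g) for g in rng.choice(mrnas, size=n_de_m, replace=False)] if n_de_m else []
        de_l = [str(g) for g in rng.choice(lncs, size=n_de_l, replace=False)] if n_de_l else []
        effects: dict[str, float] = {}
        for g in de_m + de_l:
            sign = -1.0 if rng.random() < config.frac_de_down else 1.0
            effects[g] = sign * config.de_log2fc
        de_genes[tissue] = effects
        # pair planted lncRNAs with planted mRNAs through dedicated miRNAs
        for i, lnc in enumerate(de_l):
            targets = de_m[i * config.axes_per_lncrna : (i + 1) * config.axes_per_lncrna]
            for mrna in targets:
                mirna = f"hsa-miR-{mirna_counter}-5p"
                mirna_counter += 1
                planted_axes.append(
                    PlantedAxis(
                        lncrna=lnc,
                        mirna=mirna,
                        mrna=mrna,
                        tissue=tissue,
                        concordant=bool(np.sign(effects[lnc]) == np.sign(effects[mrna])),
                    )
                )

    # Evidence rows carry coarse tissue labels ("brain" covers every brain
    # region), so an axis planted in one region is representable in any
    # sibling region where both its lncRNA and mRNA are also DE; enumerate
    # those implied axes so the truth table is complete for its own evidence.
    implied: list[PlantedAxis] = []
    seen = {(a.lncrna, a.mirna, a.mrna, a.tissue) for a in planted_axes}
    for a in planted_axes:
        label = TISSUE_EVIDENCE_LABELS.get(a.tissue)
        for other in config.groups_per_tissue:
            if other == a.tissue or TISSUE_EVIDENCE_LABELS.get(other) != label:
                continue
            eff = de_genes[other]
            if a.lncrna in eff and a.mrna in eff:
                key = (a.lncrna, a.mirna, a.mrna, other)
                if key not in seen:
                    seen.add(key)
                    implied.append(
                        PlantedAxis(
                            lncrna=a.lncrna, mirna=a.mirna, mrna=a.mrna, tissue=other,
                            concordant=bool(np.sign(eff[a.lncrna]) == np.sign(eff[a.mrna])),
                        )
                    )
    planted_axes.extend(implied)

    # keep planted signal measurable after the intensity filter
    planted_all = {g for eff in de_genes.values() for g in eff}
    for g in planted_all:
        baseline[gene_pos[g]] = rng.uniform(8.0, 11.0)

    # samples, metadata, covariates, batches
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    for tissue, (n_case, n_control) in config.groups_per_tissue.items():
        order = ["case"] * n_case + ["control"] * n_control
        # interleave conditions so cyclic batch assignment stays balanced
        interleaved: list[str] = []
        cases = iter(range(n_case))
        controls = iter(range(n_control))
        for i in range(n_case + n_control):
            pick_case = (i % 2 == 0 and i // 2 < n_case) or i // 2 >= n_control
            interleaved.append("case" if pick_case else "control")
        counters = {"case": 0, "control": 0}
        for i, cond in enumerate(interleaved):
            counters[cond] += 1
            sid = f"{tissue}_{cond}_{counters[cond]:02d}"
            sample_ids.append(sid)
            meta_rows.append({"sample": sid, "tissue": tissue, "condition": cond,
                              "batch": f"b{i % config.n_batches + 1}"})
        assert sorted(interleaved) == sorted(order)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    meta.index.name = None
    n_samples = len(sample_ids)

    cov_values: dict[str, np.ndarray] = {}
    for cov in config.covariates:
        if cov.kind == "numeric":
            z = rng.normal(0.0, 1.0, n_samples)
            meta[cov.name] = np.round(z, 6)
            cov_values[cov.name] = z * cov.effect
        else:
            levels = np.array(["A", "B"])[np.arange(n_samples) % 2]
            rng.shuffle(levels)
            meta[cov.name] = levels
            cov_values[cov.name] = (levels == "B").astype(float) * cov.effect

    # assemble log2 matrix
    x = np.tile(baseline[:, None], (1, n_samples))
    for j, sid in enumerate(sample_ids):
        tissue = meta.loc[sid, "tissue"]
        if meta.loc[sid, "condition"] == "case":
            for g, eff in de_genes[tissue].items():
                x[gene_pos[g], j] += eff
        for v in cov_values.values():
            x[:, j] += v[j]
        x[:, j] += (int(meta.loc[sid, "batch"][1:]) - 1) * config.batch_shift
    x += rng.normal(0.0, config.noise_sd, x.shape)

    outlier_sample = None
    if config.outlier is not None:
        tissue, condition, shift_sd = config.outlier
        candidates = meta.index[(meta["tissue"] == tissue) & (meta["condition"] == condition)]
        if len(candidates) == 0:
            raise ValueError(f"no sample in outlier group ({tissue}, {condition})")
        outlier_sample = candidates[0]
        j = sample_ids.index(outlier_sample)
        x[:, j] += rng.normal(0.0, shift_sd * config.noise_sd, n_total)

    matrix = pd.DataFrame(np.power(2.0, x), index=all_genes, columns=sample_ids)
    study = ExpressionStudy(matrix=matrix, scale="linear", sample_meta=meta)
    truth = TruthTable(
        de_genes=de_genes,
        planted_axes=planted_axes,
        outlier_sample=outlier_sample,
        lncrna_catalog=set(lncs),
    )
    return study, truth


def gen_interaction_catalog(
    truth: TruthTable, n_decoys: int = 50, seed: int = 0
) -> InteractionCatalog:
    """Materialize evidence tables in which every planted axis is representable.

    Each planted axis contributes a high-confidence lncRNA-miRNA record
    with the matching coarse tissue label, its miRNA to the disease set,
    and a strong-evidence miRNA-mRNA record. ``n_decoys`` additional
    records per table are added that each fail at least one downstream
    filter (low confidence, foreign tissue, weak evidence, or a miRNA
    absent from the disease set), so a correct assembly recovers exactly
    the planted concordant axes.
    """
    rng = np.random.default_rng(seed)
    lnc_mi, mi_mrna, disease = [], [], set()
    for a in truth.planted_axes:
        lnc_mi.append((a.lncrna, a.mirna, TISSUE_EVIDENCE_LABELS[a.tissue], "high"))
        mi_mrna.append((a.mirna, a.mrna, "strong"))
        disease.add(a.mirna)
    for i in range(n_decoys):
        dl, dm, dg = f"DECOYLNC{i:03d}", f"hsa-miR-9{i:03d}-3p", f"DECOYG{i:03d}"
        mode = i % 4
        if mode == 0:  # low-confidence interaction
            lnc_mi.append((dl, dm, "brain", "low"))
            mi_mrna.append((dm, dg, "strong"))
        elif mode == 1:  # tissue label matching no study tissue
            lnc_mi.append((dl, dm, "kidney", "high"))
            mi_mrna.append((dm, dg, "strong"))
        elif mode == 2:  # weak target evidence
            lnc_mi.append((dl, dm, "brain", "high"))
            mi_mrna.append((dm, dg, "weak"))
            disease.add(dm)
        else:  # miRNA not disease-associated
            label = "brain" if rng.random() < 0.5 else "peripheral blood"
            lnc_mi.append((dl, dm, label, "high"))
            mi_mrna.append((dm, dg, "strong"))
    return InteractionCatalog(
        lnc_mi=pd.DataFrame(lnc_mi, columns=["lncrna", "mirna", "tissue", "confidence"]),
        disease_mi=disease,
        mi_mrna=pd.DataFrame(mi_mrna, columns=["mirna", "mrna", "evidence"]),
    )


def gen_ppi_table(
    genes: list[str],
    hub_plan: dict[str, int],
    seed: int = 0,
    n_background: int | None = None,
) -> pd.DataFrame:
    """Emit a PPI score table realizing requested high-confidence degrees.

    Genes in ``hub_plan`` receive exactly the requested number of partners
    with score >= 0.75 (well above the 0.700 high-confidence threshold);
    partners are drawn from genes outside the plan. Background edges carry
    scores below 0.7.
    """
    if len(set(genes)) != len(genes):
        raise ValueError("gene symbols must be unique")
    pool = [g for g in genes if g not in hub_plan]
    rows: list[tuple[str, str, float]] = []
    seen: set[frozenset[str]] = set()
    rng = np.random.default_rng(seed)
    for hub in sorted(hub_plan):
        degree = hub_plan[hub]
        if degree >= len(genes):
            raise ValueError(f"requested degree {degree} for {hub} >= number of genes")
        if degree > len(pool):
            raise ValueError(f"not enough non-hub partners for {hub}")
        partners = [str(p) for p in rng.choice(pool, size=degree, replace=False)]
        for p in partners:
            rows.append((hub, p, float(np.round(rng.uniform(0.75, 0.99), 3))))
            seen.add(frozenset((hub, p)))
    n_background = 2 * len(genes) if n_background is None else n_background
    tries = 0
    while len(rows) < len(seen) + n_background and tries < 20 * n_background:
        tries += 1
        a, b = (str(g) for g in rng.choice(genes, size=2, replace=False))
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        rows.append((a, b, float(np.round(rng.uniform(0.05, 0.65), 3))))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])


def gen_gene_sets(
    genes: list[str],
    n_sets: int,
    planted_set: set[str],
    seed: int = 0,
) -> GeneSetCollection:
    """Gene-set collection over ``genes`` containing the planted set.

    The first set equals ``planted_set`` (an enrichment positive control);
    the remaining ``n_sets - 1`` sets are uniform random draws of
    comparable size.
    """
    if n_sets < 1:
        raise ValueError("need at least one set")
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {"planted_pathway": set(planted_set)}
    size = max(len(planted_set), 5)
    for i in range(1, n_sets):
        sets[f"random_set_{i:03d}"] = {str(g) for g in rng.choice(genes, size=size, replace=False)}
    return GeneSetCollection(sets=sets, universe=set(genes))
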