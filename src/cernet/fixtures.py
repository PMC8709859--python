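"""Published result tables bundled as in-memory fixtures.

The study these tables come from profiled three postmortem brain regions
(hippocampus HPC, Brodmann area 46 BA46, striatum STR) and peripheral-blood
lymphoblasts (LB) of schizophrenia patients versus controls, assembled
tissue-specific lncRNA-miRNA-mRNA competing-endogenous-RNA (ceRNA) axes,
and reported:

* the ceRNA axis table (one printed row per lncRNA-set / miRNA / mRNA-set
  combination, with tissue and shared expression direction),
* per-region top-5 hub genes from the protein-protein-interaction network
  of differentially expressed mRNAs,
* the brain/blood overlap table of differentially expressed genes.

``load_fixture`` exposes them in the shapes the analysis modules consume.
"""

from __future__ import annotations

from .cerna import CeRNAAxis

# One tuple per printed axis-table row:
# (lncRNAs, miRNA, mRNAs, tissue, direction). A row expands to the full
# cartesian product of its lncRNA and mRNA lists over the single miRNA.
CERNA_AXIS_TABLE: tuple[tuple[tuple[str, ...], str, tuple[str, ...], str, str], ...] = (
    # --- hippocampus ---
    (("DLX6-AS1",), "hsa-miR-22-3p", ("ACVR1C", "BDNF"), "HPC", "down"),
    (("DLX6-AS1",), "hsa-miR-124-3p", ("BDNF",), "HPC", "down"),
    (("DLX6-AS1",), "hsa-miR-132-3p", ("BDNF",), "HPC", "down"),
    (("DLX6-AS1",), "hsa-miR-15a-5p", ("BDNF",), "HPC", "down"),
    (("DLX6-AS1",), "hsa-miR-708-5p", ("NNAT",), "HPC", "down"),
    (("BABAM2-AS1", "NEAT1", "LINC01094"), "hsa-miR-30b-5p", ("BCL6",), "HPC", "up"),
    (("NEAT1",), "hsa-miR-9-5p", ("BCL6", "TGFBI", "TGFBR2"), "HPC", "up"),
    (("LINC01094", "NEAT1"), "hsa-miR-132-3p", ("CDKN1A",), "HPC", "up"),
    (("NEAT1",), "hsa-miR-22-3p", ("CDKN1A",), "HPC", "up"),
    (("BABAM2-AS1", "LINC01094", "NEAT1"), "hsa-miR-17-5p",
     ("CDKN1A", "TGFBR2", "VEGFA"), "HPC", "up"),
    (("NEAT1", "LINC01094"), "hsa-miR-29a-3p",
     ("FGG", "TET1", "VEGFA", "ZFP36", "TNFAIP3", "MCL1", "CD93"), "HPC", "up"),
    (("LINC01094", "NEAT1"), "hsa-miR-7-5p", ("FOS",), "HPC", "up"),
    (("NEAT1", "LINC01094"), "hsa-miR-29c-3p", ("MCL1", "FGG", "VEGFA"), "HPC", "up"),
    (("LINC01094", "MINCR", "NEAT1"), "hsa-miR-23a-3p", ("MT2A", "HMGB2"), "HPC", "up"),
    (("NEAT1",), "hsa-miR-126-3p", ("NFKBIA", "PIK3R2", "ADM", "VEGFA"), "HPC", "up"),
    (("PAX8-AS1", "LINC01094", "NEAT1"), "hsa-miR-29b-3p",
     ("TET1", "FOS", "ANGPTL4", "AQP4", "FGG", "VEGFA", "TNFAIP3", "MCL1"), "HPC", "up"),
    (("BABAM2-AS1", "PAX8-AS1", "LINC01094", "NEAT1"), "hsa-miR-20b-5p",
     ("VEGFA", "CDKN1A"), "HPC", "up"),
    (("LINC01094", "NEAT1"), "hsa-miR-195-5p", ("VEGFA", "FGF2"), "HPC", "up"),
    (("NEAT1", "DLGAP1-AS1"), "hsa-miR-15a-5p", ("VEGFA", "IL10RA", "HSPA1B"), "HPC", "up"),
    (("PAX8-AS1", "LINC01094", "NEAT1", "MINCR"), "hsa-miR-34a-5p",
     ("VEGFA", "NAMPT", "FOS", "CD44"), "HPC", "up"),
    (("NEAT1",), "hsa-miR-126-5p", ("VEGFA",), "HPC", "up"),
    (("NEAT1", "LINC01094", "DLGAP1-AS1"), "hsa-miR-15b-5p", ("VEGFA",), "HPC", "up"),
    # --- Brodmann area 46 ---
    (("NEAT1",), "hsa-miR-126-3p", ("ADM", "SOX2", "VEGFA", "MERTK", "NFKBIA"), "BA46", "up"),
    (("NEAT1", "LINC01094"), "hsa-miR-30b-5p", ("BCL6", "CAT"), "BA46", "up"),
    (("NEAT1",), "hsa-miR-22-3p", ("CDKN1A", "BMPR1B"), "BA46", "up"),
    (("LINC01094", "NEAT1"), "hsa-miR-132-3p", ("CDKN1A",), "BA46", "up"),
    (("NEAT1", "LINC01094"), "hsa-miR-17-5p", ("CDKN1A", "VEGFA"), "BA46", "up"),
    (("PAX8-AS1", "LINC01094", "NEAT1"), "hsa-miR-20b-5p", ("CDKN1A", "VEGFA"), "BA46", "up"),
    (("NEAT1",), "hsa-miR-138-5p", ("FERMT2", "VIM", "YAP1"), "BA46", "up"),
    (("ZFHX4-AS1", "LINC01094", "NEAT1"), "hsa-miR-7-5p", ("FOS",), "BA46", "up"),
    (("NEAT1", "MINCR", "LINC01094", "ZFHX4-AS1"), "hsa-miR-23a-3p",
     ("HMGB2", "MT2A"), "BA46", "up"),
    (("NEAT1", "LINC01094"), "hsa-miR-29a-3p",
     ("MCL1", "ZFP36", "TET1", "FGG", "VEGFA", "TNFAIP3", "CD93"), "BA46", "up"),
    (("NEAT1", "PAX8-AS1", "MINCR", "LINC01094"), "hsa-miR-98-5p", ("NRAS",), "BA46", "up"),
    (("MINCR", "PAX8-AS1", "LINC01094", "ZFHX4-AS1", "NEAT1"), "hsa-miR-34a-5p",
     ("SOX2", "VEGFA", "NAMPT", "CD44", "FOS"), "BA46", "up"),
    (("NEAT1", "PAX8-AS1", "LINC01094", "MINCR"), "hsa-let-7g-5p", ("TGFBR1",), "BA46", "up"),
    (("LINC01094", "NEAT1"), "hsa-miR-15b-5p", ("VEGFA",), "BA46", "up"),
    (("LINC01094", "PAX8-AS1", "NEAT1"), "hsa-miR-29b-3p",
     ("VEGFA", "MCL1", "ELAVL1", "TNFAIP3", "FOS", "FGG", "AQP4", "ANGPTL4", "TET1"),
     "BA46", "up"),
    (("NEAT1", "LINC01094"), "hsa-miR-29c-3p", ("VEGFA", "MCL1", "FGG"), "BA46", "up"),
    (("NEAT1",), "hsa-miR-126-5p", ("VEGFA",), "BA46", "up"),
    (("ZFHX4-AS1", "NEAT1"), "hsa-miR-9-5p", ("VIM", "BCL6", "ELAVL1", "TGFBI"), "BA46", "up"),
    (("NEAT1", "MINCR"), "hsa-miR-124-3p", ("VIM",), "BA46", "up"),
    (("NEAT1", "LINC01094"), "hsa-miR-195-5p", ("YAP1", "VEGFA", "FGF2"), "BA46", "up"),
    (("NEAT1",), "hsa-miR-15a-5p", ("YAP1", "VEGFA", "IL10RA", "UCP2", "HSPA1B"), "BA46", "up"),
    # --- striatum ---
    (("DLX6-AS1",), "hsa-miR-34a-5p", ("EPHA5",), "STR", "down"),
    (("NEAT1",), "hsa-miR-126-3p", ("ADM", "VEGFA", "NFKBIA", "PIK3R2"), "STR", "up"),
    (("LINC01094", "NEAT1"), "hsa-miR-30b-5p", ("BCL6",), "STR", "up"),
    (("NEAT1",), "hsa-miR-22-3p", ("CDKN1A",), "STR", "up"),
    (("NEAT1", "LINC01094"), "hsa-miR-132-3p", ("CDKN1A",), "STR", "up"),
    (("MINCR", "LINC01094", "NEAT1"), "hsa-miR-23a-3p", ("FAS", "HMGB2"), "STR", "up"),
    (("NEAT1", "LINC01094"), "hsa-miR-7-5p", ("FOS",), "STR", "up"),
    (("LINC01094", "MINCR", "PAX8-AS1", "NEAT1"), "hsa-miR-34a-5p",
     ("FOS", "VEGFA", "NAMPT", "CD44"), "STR", "up"),
    (("LINC01094", "NEAT1"), "hsa-miR-29a-3p",
     ("MCL1", "VEGFA", "TNFAIP3", "CD93", "SPARC", "ZFP36", "FGG"), "STR", "up"),
    (("MINCR", "PAX8-AS1", "LINC01094", "NEAT1"), "hsa-let-7g-5p", ("TGFBR1",), "STR", "up"),
    (("DLGAP1-AS1", "NEAT1"), "hsa-miR-15a-5p",
     ("UCP2", "VEGFA", "IL10RA", "HSPA1B", "YAP1"), "STR", "up"),
    (("NEAT1", "LINC01094"), "hsa-miR-17-5p", ("VEGFA", "CDKN1A"), "STR", "up"),
    (("PAX8-AS1", "NEAT1", "LINC01094"), "hsa-miR-20b-5p", ("VEGFA", "CDKN1A"), "STR", "up"),
    (("DLGAP1-AS1", "LINC01094", "NEAT1"), "hsa-miR-15b-5p", ("VEGFA",), "STR", "up"),
    (("LINC01094", "PAX8-AS1", "NEAT1"), "hsa-miR-29b-3p",
     ("VEGFA", "MCL1", "ELAVL1", "SPARC", "ANGPTL4", "AQP4", "FGG", "FOS", "TNFAIP3"),
     "STR", "up"),
    (("LINC01094", "NEAT1", "XIST"), "hsa-miR-29c-3p",
     ("VEGFA", "MCL1", "FGG", "SPARC"), "STR", "up"),
    (("NEAT1",), "hsa-miR-126-5p", ("VEGFA",), "STR", "up"),
    (("LINC01094", "NEAT1"), "hsa-miR-195-5p", ("VEGFA", "YAP1", "FGF2"), "STR", "up"),
    (("NEAT1",), "hsa-miR-9-5p", ("VIM", "ELAVL1", "BCL6", "TGFBI"), "STR", "up"),
    (("NEAT1", "MINCR"), "hsa-miR-124-3p", ("VIM",), "STR", "up"),
    (("NEAT1",), "hsa-miR-138-5p", ("VIM", "YAP1"), "STR", "up"),
    # --- lymphoblasts ---
    (("MALAT1",), "hsa-miR-9-5p", ("STARD13",), "LB", "up"),
)

# Per-region top-5 hub genes (highest PPI degree among DE mRNAs).
HUB_GENES: dict[str, tuple[str, ...]] = {
    "HPC": ("VEGFA", "FGF2", "CD44", "BDNF", "FOS"),
    "BA46": ("VEGFA", "CD44", "FGF2", "NRAS", "SOX2"),
    "STR": ("VEGFA", "ELAVL1", "SPARC", "FGG", "ZFP36"),
}

# Brain/blood overlap table: region combination -> (DE mRNAs, DE lncRNAs).
BRAIN_BLOOD_OVERLAP: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] = {
    "HPC and LB": (
        ("ADM", "CLEC2B", "F13A1", "HLA-DQB1", "HLA-DRB1", "HLA-DRB3",
         "HLA-DRB4", "HLA-DRB5"),
        (),
    ),
    "BA46 and LB": (
        ("ADM", "CSF2RB", "F13A1", "HLA-DQB1", "HLA-DRB1", "HLA-DRB3",
         "HLA-DRB4", "HLA-DRB5", "RHPN2"),
        (),
    ),
    "STR and LB": (
        ("ADM", "CLEC2B", "CSF2RB", "DDX3Y", "EIF1AY", "F13A1", "HLA-DQB1",
         "HLA-DRB1", "HLA-DRB3", "HLA-DRB4", "HLA-DRB5", "KDM5D", "RPS4Y1",
         "USP9Y"),
        ("XIST",),
    ),
    "HPC, BA46, and LB": (
        ("ADM", "F13A1", "HLA-DQB1", "HLA-DRB1", "HLA-DRB3", "HLA-DRB4",
         "HLA-DRB5"),
        (),
    ),
    "HPC, STR, and LB": (
        ("ADM", "CLEC2B", "F13A1", "HLA-DQB1", "HLA-DRB1", "HLA-DRB3",
         "HLA-DRB4", "HLA-DRB5"),
        (),
    ),
    "BA46, STR, and LB": (
        ("ADM", "CSF2RB", "F13A1", "HLA-DQB1", "HLA-DRB1", "HLA-DRB3",
         "HLA-DRB4", "HLA-DRB5"),
        (),
    ),
    "HPC, BA46, STR, and LB": (
        ("ADM", "F13A1", "HLA-DQB1", "HLA-DRB1", "HLA-DRB3", "HLA-DRB4",
         "HLA-DRB5"),
        (),
    ),
}


def expand_axis_table(tissues: tuple[str, ...] | None = None) -> list[CeRNAAxis]:
    """Expand the printed axis-table rows into individual ceRNA triples.

    Each row contributes the cartesian product of its lncRNAs and mRNAs over
    its single miRNA. Duplicate triples within a tissue (the same triple can
    be implied by more than one printed row) are collapsed, keeping the first
    occurrence.
    """
    seen: set[tuple[str, str, str, str]] = set()
    axes: list[CeRNAAxis] = []
    for lncs, mirna, mrnas, tissue, direction in CERNA_AXIS_TABLE:
        if tissues is not None and tissue not in tissues:
            continue
        for lnc in lncs:
            for mrna in mrnas:
                key = (lnc, mirna, mrna, tissue)
                if key in seen:
                    continue
                seen.add(key)
                axes.append(
                    CeRNAAxis(
                        lncrna=lnc,
                        mirna=mirna,
                        mrna=mrna,
                        tissue=tissue,
                        lnc_direction=direction,
                        mrna_direction=direction,
                    )
                )
    return axes


def load_fixture(name: str):
    """Return a bundled published-table fixture.

    Parameters
    ----------
    name
        ``"table2"`` — the ceRNA axis table expanded to individual triples
        (list of :class:`~cernet.cerna.CeRNAAxis`);
        ``"table1"`` — brain/blood overlap sets, mapping the printed region
        combination to ``{"mrna": set, "lncrna": set}``;
        ``"hub_lists"`` — per-region top-5 hub gene tuples;
        ``"lb_axis"`` — the single lymphoblast axis.
    """
    if name == "table2":
        return expand_axis_table()
    if name == "table1":
        return {
            combo: {"mrna": set(mrnas), "lncrna": set(lncs)}
            for combo, (mrnas, lncs) in BRAIN_BLOOD_OVERLAP.items()
        }
    if name == "hub_lists":
        return dict(HUB_GENES)
    if name == "lb_axis":
        (axis,) = expand_axis_table(tissues=("LB",))
        return axis
    raise KeyError(f"unknown fixture {name!r}")
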