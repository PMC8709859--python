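#!/usr/bin/env python
"""Rank PPI hub genes, rebuild the hub subnetwork, and compute DEG overlaps.

A protein-protein-interaction score table is generated over each tissue's
DE mRNAs (with planted high-confidence hubs), thresholded at the 0.700
high-confidence score, and the top-5 degree genes are taken as hubs. The
cross-tissue hub union restricts the ceRNA axes to the hub subnetwork,
whose upstream lncRNAs and miRNAs are the "key" regulators. DEG symbol
sets are intersected across tissues (Venn regions and the brain/blood
overlap).

Reads results/de/ and results/cerna/, writes to results/network/.
"""

import argparse
from pathlib import Path

import pandas as pd

from cernet import io, network
from cernet.synthetic import gen_ppi_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--de", type=Path, default=Path("results/de"))
    ap.add_argument("--cerna", type=Path, default=Path("results/cerna"))
    ap.add_argument("--out", type=Path, default=Path("results/network"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    de_sets, axes_by_tissue, hub_reports = {}, {}, {}
    for i, path in enumerate(sorted(args.de.glob("de_*.tsv"))):
        tissue = path.stem.removeprefix("de_")
        table = pd.read_csv(path, sep="\t", index_col="gene")
        de = table[table["direction"] != "ns"]
        de_sets[tissue] = set(de.index)
        demrnas = sorted(de.index[de["gene_class"] == "mRNA"])
        axes_by_tissue[tissue] = io.read_axes(args.cerna / f"axes_{tissue}.tsv")
        net_mrnas = sorted({a.mrna for a in axes_by_tissue[tissue]})
        if not net_mrnas or len(demrnas) < 2:
            continue
        planned = net_mrnas[:5]
        top = min(len(demrnas) - 1, 12)
        plan = {g: top - j for j, g in enumerate(planned) if top - j >= 1}
        ppi = gen_ppi_table(demrnas, plan, seed=args.seed + 10 + i)
        ppi.to_csv(args.out / f"ppi_{tissue}.tsv", sep="\t", index=False)
        graph = network.build_ppi_subgraph(set(demrnas), ppi)
        hub_reports[tissue] = network.rank_hubs(graph, k=5)
        print(f"{tissue}: top-5 hubs {hub_reports[tissue].hubs}")

    hub_union = sorted({h for r in hub_reports.values() for h in r.hubs})
    sub = network.reconstruct_subnetwork(axes_by_tissue, set(hub_union))
    for tissue, net in sub["networks"].items():
        io.write_graphml(net, args.out / f"subcerna_{tissue}.graphml")
        io.write_sif(net, args.out / f"subcerna_{tissue}.sif")
    print(
        f"hub union: {len(hub_union)} genes; subnetwork keeps "
        f"{len(sub['key_lncrnas'])} key lncRNAs, {len(sub['key_mirnas'])} key miRNAs, "
        f"{len(sub['key_mrnas'])} key mRNAs"
    )

    venn = network.overlap_analysis(de_sets)
    io.write_json(
        {
            "exclusive_regions": {"&".join(k): sorted(v)
                                  for k, v in venn["exclusive_regions"].items()},
            "brain_blood": sorted(venn.get("brain_blood", set())),
            "union": sorted(venn["union"]),
            "hub_union": hub_union,
            "key_lncrnas": sub["key_lncrnas"],
            "key_mirnas": sub["key_mirnas"],
        },
        args.out / "overlap_and_hubs.json",
    )
    print(
        f"DEGs dysregulated in both brain and blood: "
        f"{len(venn.get('brain_blood', set()))} of {len(venn['union'])} total DEGs"
    )


if __name__ == "__main__":
    main()
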