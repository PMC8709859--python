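#!/usr/bin/env python
"""Recompute the countable published results from the bundled table fixtures.

Expands the printed ceRNA axis table into triples and reproduces, with the
package's own operations: the lymphoblast network size, the brain/blood
DEG overlap, the hub-gene union, the hub subnetwork's key-transcript
counts, and the number of axes shared by all three brain regions.

Writes results/published/counts.json.
"""

import argparse
from pathlib import Path

from cernet import cerna, io, network
from cernet.cerna import build_network, prune_discordant
from cernet.fixtures import load_fixture


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results/published"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    axes = load_fixture("table2")
    grouped: dict[str, list] = {}
    for a in axes:
        grouped.setdefault(a.tissue, []).append(a)
    for tissue, tissue_axes in grouped.items():
        s = network.network_summary(build_network(prune_discordant(tissue_axes), tissue))
        print(f"{tissue}: {len(tissue_axes)} triples -> {s['nodes']} nodes "
              f"({s['lncRNAs']}/{s['miRNAs']}/{s['mRNAs']}), {s['edges']} edges")

    common = cerna.common_axes({t: grouped[t] for t in ("HPC", "BA46", "STR")})
    print(f"axes common to HPC, BA46 and STR: {len(common)}")

    table1 = load_fixture("table1")
    pairwise = [table1[k]["mrna"] for k in ("HPC and LB", "BA46 and LB", "STR and LB")]
    union = set().union(*pairwise)
    core = set.intersection(*pairwise)
    print(f"DEmRNAs dysregulated in both brain and blood: {len(union)}")
    print(f"shared by all four tissues: {sorted(core)}")

    hubs = set().union(*load_fixture("hub_lists").values())
    sub = network.reconstruct_subnetwork(grouped, hubs)
    print(f"hub union: {len(hubs)} genes; subnetwork: {len(sub['key_lncrnas'])} "
          f"key lncRNAs, {len(sub['key_mirnas'])} key miRNAs")

    io.write_json(
        {
            "lb_network": network.network_summary(build_network(grouped["LB"], "LB")),
            "common_brain_axes": len(common),
            "brain_blood_demrnas": len(union),
            "four_way_core": sorted(core),
            "hub_union": sorted(hubs),
            "key_lncrnas": sub["key_lncrnas"],
            "key_mirnas": sub["key_mirnas"],
        },
        args.out / "counts.json",
    )


if __name__ == "__main__":
    main()
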