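#!/usr/bin/env python
"""Gene-set over-representation of the ceRNA-network mRNAs.

Builds a gene-set collection over the filtered-gene universe containing a
positive-control set equal to the network mRNAs plus random sets, then
ranks sets by one-sided Fisher exact enrichment with BH adjustment. The
positive control must rank first; random sets calibrate the null.

Reads results/cerna/ and results/de/universe.txt, writes to
results/enrichment/.
"""

import argparse
from pathlib import Path

from cernet import enrichment, io
from cernet.synthetic import gen_gene_sets


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--de", type=Path, default=Path("results/de"))
    ap.add_argument("--cerna", type=Path, default=Path("results/cerna"))
    ap.add_argument("--out", type=Path, default=Path("results/enrichment"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    universe = sorted(
        (args.de / "universe.txt").read_text().split()
    )
    query = set()
    for path in sorted(args.cerna.glob("axes_*.tsv")):
        query |= {a.mrna for a in io.read_axes(path)}
    if not query:
        print("no ceRNA-network mRNAs; nothing to enrich")
        return

    collection = gen_gene_sets(universe, n_sets=20, planted_set=query,
                               seed=args.seed + 20)
    io.write_gmt(collection, args.out / "gene_sets.gmt")
    table = enrichment.fisher_enrich(query, collection)
    table.to_csv(args.out / "enrichment.tsv", sep="\t", index=False)
    top = enrichment.top_terms(table, k=5)
    print(f"query: {len(query)} network mRNAs against {len(collection.sets)} sets "
          f"(universe {len(universe)})")
    for row in top.itertuples(index=False):
        star = "*" if row.significant else " "
        print(f"  {star} {row.term}: k={row.k}/{row.K}, p={row.p:.3g}, "
              f"adjP={row.adj_p:.3g}")


if __name__ == "__main__":
    main()
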