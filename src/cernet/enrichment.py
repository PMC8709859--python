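"""Gene-set over-representation analysis (one-sided Fisher exact + BH).

For a query of n genes drawn from a universe of N genes, and a gene set of
K universe members of which k overlap the query, the enrichment p-value is
the upper hypergeometric tail P(X >= k), i.e. the one-sided Fisher exact
test on the 2x2 table [[k, n-k], [K-k, N-K-n+k]].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

__all__ = ["GeneSetCollection", "fisher_enrich", "top_terms"]


@dataclass
class GeneSetCollection:
    """Named gene sets with the background universe they refer to."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("gene set names must be unique")
        # membership outside the universe never contributes to a test
        self.sets = {name: set(s) & self.universe for name, s in self.sets.items()}

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        return GeneSetCollection(
            sets={n: s & universe for n, s in self.sets.items()}, universe=set(universe)
        )


def fisher_enrich(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Rank gene sets by one-sided Fisher exact enrichment of ``query``.

    Query symbols outside the universe are dropped (the dropped count is
    recorded in ``attrs["dropped_from_query"]``). Rows are ranked by p
    ascending with ties broken by odds ratio descending; ``adj_p`` is BH
    across all sets in the collection.
    """
    coll = collection if universe is None else collection.restrict(universe)
    n_universe = len(coll.universe)
    if n_universe == 0:
        raise ValueError("empty universe")
    q = set(query) & coll.universe
    dropped = len(set(query)) - len(q)
    rows = []
    for name, members in coll.sets.items():
        k = len(q & members)
        n, big_k = len(q), len(members)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n))
        a, b = k, n - k
        c, d = big_k - k, n_universe - big_k - n + k
        odds = np.inf if b * c == 0 and a * d > 0 else (
            (a * d) / (b * c) if b * c else np.nan
        )
        rows.append((name, k, n, big_k, n_universe, odds, min(p, 1.0)))
    table = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "odds_ratio", "p"]
    )
    table["adj_p"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    table = table.sort_values(
        ["p", "odds_ratio"], ascending=[True, False], kind="stable"
    ).reset_index(drop=True)
    table.attrs["dropped_from_query"] = dropped
    return table


def top_terms(table: pd.DataFrame, k: int = 5, alpha: float = 0.05) -> pd.DataFrame:
    """First ``k`` ranked terms with an adjP < ``alpha`` significance flag."""
    out = table.head(k).copy()
    out["significant"] = out["adj_p"] < alpha
    return out
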