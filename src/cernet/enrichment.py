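"""Gene-set over-representation: upper-tail hypergeometric, p < 0.05 screen.

Collections are user-supplied GO/KEGG-style GMT files; there is no live
term database.  BH q-values are reported alongside, but the significance
flag follows the raw p < 0.05 screening standard.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import DomainError, InputError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        if any(not name for name in self.sets):
            raise InputError("empty gene-set name")
        trimmed = {
            name: members & self.universe for name, members in self.sets.items()
        }
        dropped = sum(
            len(self.sets[n]) - len(trimmed[n]) for n in self.sets
        )
        if dropped:
            logger.info("trimmed %d set members outside the universe", dropped)
        self.sets = trimmed


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(overlap >= k | K, n, N)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise DomainError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(query: set[str], collection: GeneSetCollection,
           alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Test the query against every set; rank by p, flag p < alpha.

    Query ids outside the universe are dropped with a log message.  Output
    columns: set_name, k (overlap), K (set size), n (query size),
    N (universe size), p, q, significant.
    """
    outside = query - collection.universe
    if outside:
        logger.info("dropping %d query ids outside the universe", len(outside))
    query = query & collection.universe
    N, n = len(collection.universe), len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name]
        K = len(members)
        k = len(query & members)
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N,
                     "p": hypergeom_p(k, K, n, N)})
    table = pd.DataFrame(
        rows, columns=["set_name", "k", "K", "n", "N", "p"]
    )
    if len(table):
        table["q"] = bh_adjust(table["p"].to_numpy())
        table["significant"] = table["p"] < alpha
        table = table.sort_values(
            ["p", "set_name"], kind="stable"
        ).reset_index(drop=True)
    else:
        table["q"] = []
        table["significant"] = []
    return table
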