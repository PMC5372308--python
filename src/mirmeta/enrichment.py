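"""Consensus target sets and hypergeometric over-representation.

Target genes predicted by several sources are reduced to a consensus
list (genes present in at least ``min_sources`` sources; the default is
all sources, i.e. the strict intersection) together with the full Venn
region counts.  Gene-set enrichment of a query list uses the one-sided
hypergeometric tail P(X >= k) over a stated universe, with BH q-values
reported alongside the raw-p significance flag at the configured cutoff.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneSetDB

log = logging.getLogger("mirmeta")


def consensus_targets(
    sources: GeneSetDB, min_sources: int | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Genes present in at least ``min_sources`` prediction sources.

    ``min_sources=None`` (or 0) means all sources.  Also returns the
    Venn-region table: for every non-empty source combination, the count
    of genes present in exactly those sources.
    """
    n_src = len(sources)
    if min_sources is None or min_sources == 0:
        min_sources = n_src
    if not 1 <= min_sources <= n_src:
        raise ValueError(f"min_sources must be in [1, {n_src}]")
    names = sources.set_names
    membership: dict[str, frozenset] = {}
    for name in names:
        for g in sources.sets[name]:
            membership[g] = membership.get(g, frozenset()) | {name}
    consensus = sorted(g for g, m in membership.items() if len(m) >= min_sources)

    region_counts = {}
    for r in range(1, n_src + 1):
        for combo in combinations(names, r):
            key = frozenset(combo)
            region_counts[key] = sum(1 for m in membership.values() if m == key)
    venn = pd.DataFrame(
        {
            "sources": ["&".join(sorted(k)) for k in region_counts],
            "n_sources": [len(k) for k in region_counts],
            "n_genes": list(region_counts.values()),
        }
    ).sort_values(["n_sources", "sources"], ignore_index=True)
    log.info(
        "consensus_targets: %d genes in >= %d of %d sources",
        len(consensus), min_sources, n_src,
    )
    return consensus, venn


def hypergeometric_enrichment(
    query: list[str], db: GeneSetDB, cutoff: float = 0.05
) -> pd.DataFrame:
    """Over-representation of a query gene list in each set of a database.

    For a universe of N genes, a set of K, and a query of n with overlap
    k, p = P(X >= k) for X ~ Hypergeometric(N, K, n).  Rows are sorted
    ascending by p (set name as tie-break); ``significant`` flags raw
    p < cutoff; BH q is reported alongside.
    """
    universe = set(db.universe)
    q = set(query)
    dropped = q - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe dropped", stacklevel=2
        )
        q &= universe
    if not q:
        raise ValueError("query is empty after restriction to the universe")
    N = len(universe)
    n = len(q)
    rows = []
    for name in db.set_names:
        members = set(db.sets[name])
        K = len(members)
        k = len(q & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, p))
    table = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_hyper"])
    table["q_bh"] = multipletests(table["p_hyper"], method="fdr_bh")[1]
    table["significant"] = table["p_hyper"] < cutoff
    table = table.sort_values(
        ["p_hyper", "set_name"], ascending=[True, True], ignore_index=True
    )
    return table
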