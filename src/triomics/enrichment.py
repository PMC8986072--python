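"""Overlap-based gene-set enrichment: one-sided hypergeometric test per set
with Benjamini-Hochberg FDR across the collection, ranked by (q, p, name).

For an input set of ``n`` genes drawn from a universe of ``N``, a collection
set of size ``K`` (after intersection with the universe) and an observed
overlap ``k``, the p value is ``P[X >= k]`` for ``X ~ Hypergeom(N, K, n)``.
Gene identifiers are matched case-insensitively.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg
from .io import GeneSetCollection, ValidationError

logger = logging.getLogger("triomics")


def hypergeom_overlap_p(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric overlap probability P[X >= k]."""
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(input_set, collection: GeneSetCollection,
           universe) -> pd.DataFrame:
    """Test the input gene set against every set in the collection."""
    universe = {g.upper() for g in universe}
    query = {g.upper() for g in input_set}
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty input gene set")
    if not query <= universe:
        raise ValidationError(
            f"input set not contained in universe: "
            f"{sorted(query - universe)[:5]}")
    N, n = len(universe), len(query)
    rows = []
    for name in collection.sets:
        members = {g.upper() for g in collection.sets[name]} & universe
        k = len(members & query)
        rows.append({"set_name": name, "overlap": k, "set_size": len(members),
                     "input_size": n, "universe_size": N,
                     "p_value": hypergeom_overlap_p(k, N, len(members), n)})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_q"] = benjamini_hochberg(out["p_value"].to_numpy())
        out = out.sort_values(["fdr_q", "p_value", "set_name"],
                              kind="stable").reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
    logger.info("enrichment: %d sets tested, universe %d, input %d",
                len(out), N, n)
    return out


def top_k(results: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Stable head-k of an enrichment table by its ranking."""
    if k < 0:
        raise ValidationError("k must be >= 0")
    return results.head(k).reset_index(drop=True)
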