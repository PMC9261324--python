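"""Hypergeometric over-representation analysis (ORA).

Tests a query gene list against user-supplied gene-set collections (GMT),
each collection forming its own BH family, with a significance rule of
adjusted p below the FDR cut AND overlap count strictly greater than a
minimum.  The upper-tail probability is computed stably in log space.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import special

from .diffexpr import bh_adjust

log = logging.getLogger("agecoex")


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), via log-gamma summation.

    N is the universe size, K the set size, n the query size, k the
    observed overlap.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ValueError(f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_terms = (
        _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(special.logsumexp(log_terms))))


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return special.gammaln(n + 1) - special.gammaln(k + 1) - special.gammaln(n - k + 1)


def ora(
    query,
    sets: dict[str, set[str]],
    universe,
    fdr: float = 0.05,
    min_count: int = 6,
) -> pd.DataFrame:
    """Over-representation of `query` in each gene set within `universe`.

    Query genes outside the universe are dropped with a warning; every set
    is intersected with the universe and sets with no query overlap are
    reported with k = 0 omitted (one row per set with k >= 1).  BH is
    applied across all tested sets in this collection; the significance
    flag requires adjusted p < `fdr` and k strictly greater than
    `min_count`.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    dropped = query - universe
    if dropped:
        log.warning("ora: %d query genes outside universe dropped", len(dropped))
    query &= universe
    if not query:
        raise ValueError("no query genes remain inside the universe")
    N, n = len(universe), len(query)
    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        overlap = sorted(members & query)
        k, K = len(overlap), len(members)
        if k == 0:
            continue
        rows.append(
            {
                "set": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeometric_upper_tail(k, K, n, N),
                "overlap": ",".join(overlap),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set", "k", "K", "n", "N", "p", "adj_p", "significant", "overlap"]
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["adj_p"] < fdr) & (out["k"] > min_count)
    out = out.sort_values(["adj_p", "set"], kind="stable").reset_index(drop=True)
    return out[["set", "k", "K", "n", "N", "p", "adj_p", "significant", "overlap"]]
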