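"""Over-representation analysis of differential sets against gene-set files.

An explicit hypergeometric upper-tail test with Benjamini-Hochberg
adjustment over all tested terms.  The universe is the quantified
(post-filter) feature space, not the genome; site-level foregrounds should
be mapped to parent proteins and deduplicated *before* calling in, so a
protein with several regulated sites counts once.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Set

import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(n, K) <= N and n <= N and K <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def ora(foreground: Set[str], universe: Set[str],
        gene_sets: Mapping[str, Iterable[str]],
        alpha_adjusted: float = 0.05,
        restrict_to_annotated: bool = True) -> pd.DataFrame:
    """One hypergeometric test per term with at least one foreground hit.

    ``restrict_to_annotated`` (default) intersects both the universe and
    the foreground with the union of all gene-set members before testing,
    the convention of standard ORA tools; with ``False`` every quantified
    feature counts against the terms.  Results are BH-adjusted over all
    tested terms and sorted by p.
    """
    if not universe:
        raise ValueError("universe is empty")
    if not foreground <= universe:
        raise ValueError("foreground must be a subset of the universe")
    if restrict_to_annotated:
        annotated = set().union(*(set(m) for m in gene_sets.values())) if gene_sets else set()
        universe = universe & annotated
        foreground = foreground & annotated
    N = len(universe)
    n = len(foreground)
    rows = []
    for term, members in gene_sets.items():
        term_universe = set(members) & universe
        K = len(term_universe)
        hits = foreground & term_universe
        k = len(hits)
        if k == 0:
            continue
        rows.append({"term": term, "k": k, "n": n, "K": K, "N": N,
                     "p": hypergeom_upper_tail(k, K, n, N),
                     "members": ";".join(sorted(hits))})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjust"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["p_adjust"] < alpha_adjusted
        out = out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
    else:
        out = pd.DataFrame(columns=["term", "k", "n", "K", "N", "p", "members",
                                    "p_adjust", "significant"])
    return out
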