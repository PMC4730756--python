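"""Term over-representation of marker sets against the expressed background.

For a term annotating K of N background genes, with k of the n marker genes
carrying it, the plain enrichment p-value is the hypergeometric upper tail
P(X >= k).  The default here is the more conservative EASE variant, which
removes one observed success (tail at k-1, with p = 1 whenever k <= 1) —
the behaviour of the annotation tool the study used.  q-values are
Benjamini-Hochberg over the tested terms and significance is strict
(q < threshold).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ganglimark.diffexp import bh_adjust


def _check_args(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= k <= min(K, n) and k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent enrichment arguments k={k} K={K} n={n} N={N}")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n); in (0, 1]."""
    _check_args(k, K, n, N)
    if k == 0:
        return 1.0
    p = float(hypergeom.sf(k - 1, N, K, n))
    return min(max(p, 5e-324), 1.0)


def ease_tail(k: int, K: int, n: int, N: int) -> float:
    """EASE-adjusted tail: plain tail at k-1; p = 1 for k <= 1."""
    _check_args(k, K, n, N)
    if k <= 1:
        return 1.0
    return hypergeom_upper_tail(k - 1, K, n, N)


def enrich_terms(
    marker_genes,
    background_genes,
    term_map: dict[str, set[str]],
    q_threshold: float = 0.05,
    ease: bool = True,
) -> pd.DataFrame:
    """Test every term hitting >= 1 marker gene for over-representation.

    Parameters
    ----------
    marker_genes, background_genes : iterables of gene ids
        The marker set and the expressed-gene background; markers must be a
        subset of the background.
    term_map : dict
        gene id -> set of term ids; genes outside the background are
        ignored.
    q_threshold : float
        Strict BH significance cutoff (flagged as ``significant``).
    ease : bool
        Use the EASE (k-1) tail (default) or the plain hypergeometric tail.

    Returns
    -------
    DataFrame with one row per tested term: k, K, n, N, p, q, significant;
    sorted by p.
    """
    background = set(background_genes)
    markers = set(marker_genes)
    missing = markers - background
    if missing:
        raise ValueError(
            f"marker gene(s) absent from background: {sorted(missing)[:5]}"
        )
    N = len(background)
    n = len(markers)
    term_genes: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in background:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)
    tail = ease_tail if ease else hypergeom_upper_tail
    rows = []
    for term in sorted(term_genes):
        genes = term_genes[term]
        k = len(genes & markers)
        if k == 0:
            continue
        K = len(genes)
        rows.append((term, k, K, n, N, tail(k, K, n, N)))
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["p", "term"]).reset_index(drop=True)
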