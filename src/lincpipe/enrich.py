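"""Over-representation analysis of gene sets against a term annotation.

A generic hypergeometric test per term (with an optional EASE-style
conservative variant that scores the overlap as k-1), BH-adjusted within
each term category. Stands in for web-service annotation tools while keeping
the same statistical form.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Set, Tuple

import pandas as pd
from scipy.stats import hypergeom

BIOLOGICAL_PROCESS = "biological_process"
PATHWAY = "pathway"


@dataclass
class TermMap:
    """term_id -> (term_name, category, frozenset of gene ids)."""

    terms: Dict[str, Tuple[str, str, frozenset]]

    def __len__(self) -> int:
        return len(self.terms)

    def categories(self) -> set:
        return {cat for _, cat, _ in self.terms.values()}

    def to_frames(self):
        """(gene->term map, term-description) frames for TSV output."""
        pairs = [
            {"gene_id": g, "term_id": tid}
            for tid, (_, _, genes) in sorted(self.terms.items())
            for g in sorted(genes)
        ]
        names = [
            {"term_id": tid, "term_name": name, "category": cat}
            for tid, (name, cat, _) in sorted(self.terms.items())
        ]
        return pd.DataFrame(pairs), pd.DataFrame(names)


def hypergeom_enrich(
    query: Set[str],
    terms: TermMap,
    universe: Set[str],
    ease: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    For a term with K genes in a universe of N, and a query of n genes of
    which k fall in the term, p is the upper tail P(X >= k) of
    Hypergeom(N, K, n). With ``ease`` the overlap is scored as k-1
    (floored at 0), the conservative variant popularised by DAVID. q is BH
    across terms within each category; rows are sorted by p.

    Returns a frame with columns term_id, term_name, category, k, K, n, N,
    p, q, significant (raw p < alpha).
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query set")
    if not universe:
        raise ValueError("empty universe")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")

    N = len(universe)
    n = len(query)
    rows = []
    for tid, (name, cat, genes) in terms.terms.items():
        term_genes = genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(query & term_genes)
        k_eff = max(k - 1, 0) if ease else k
        # sf(k-1) = P(X >= k)
        p = float(hypergeom.sf(k_eff - 1, N, K, n))
        p = min(p, 1.0)
        rows.append(
            {"term_id": tid, "term_name": name, "category": cat, "k": k, "K": K, "n": n, "N": N, "p": p}
        )
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "category", "k", "K", "n", "N", "p"])
    if len(df) == 0:
        df["q"] = []
        df["significant"] = []
        return df
    from .diffexp import bh_adjust

    df["q"] = 1.0
    for cat in df["category"].unique():
        mask = df["category"] == cat
        df.loc[mask, "q"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    df["significant"] = df["p"] < alpha
    return df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
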