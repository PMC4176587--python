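"""Hypergeometric over-representation of annotation terms in gene clusters.

For a cluster of n genes drawn from a universe of N genes of which K
carry a term, the enrichment p-value is the upper hypergeometric tail
P(X >= k) for the observed overlap k.  The test is the plain
(unconditional) single-term test; no ontology-graph conditioning is
applied.  The universe is the set of genes actually measured on the
array, not all annotated genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh


@dataclass
class TermMap:
    """Annotation terms (term id -> gene set) over a gene universe."""

    terms: dict[str, set[str]]
    universe: set[str]

    def validate(self) -> None:
        for term, genes in self.terms.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"term {term!r} has genes outside the universe: {sorted(extra)[:5]}"
                )

    def restricted_to(self, universe: set[str]) -> "TermMap":
        """Intersect every term with a new universe (the measured genes)."""
        return TermMap(
            terms={t: g & universe for t, g in self.terms.items()},
            universe=set(universe),
        )


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    # survival function at k-1 gives the inclusive upper tail
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_clusters(
    assignments: pd.Series,
    termmap: TermMap,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Test every (cluster, term) pair for over-representation.

    ``assignments`` maps gene id -> cluster label, with negative labels
    meaning unassigned (skipped).  Terms are first restricted to the
    universe; terms smaller than ``min_term_size`` after restriction are
    not tested.  BH adjustment is applied across terms within each
    cluster; results are sorted by raw p.
    """
    if not termmap.universe:
        raise ValueError("empty gene universe")
    universe = set(termmap.universe)
    outside = set(assignments.index) - universe
    if outside:
        raise ValueError(f"cluster genes outside universe: {sorted(outside)[:5]}")
    N = len(universe)
    terms = {
        t: g for t, g in termmap.terms.items() if len(g) >= min_term_size
    }
    rows = []
    for cluster, sub in assignments.groupby(assignments):
        if isinstance(cluster, (int, float)) and cluster < 0:
            continue
        members = set(sub.index)
        n = len(members)
        for term, term_genes in terms.items():
            k = len(members & term_genes)
            K = len(term_genes)
            rows.append({
                "cluster": cluster, "term": term, "k": k, "K": K, "n": n, "N": N,
                "p_raw": hypergeom_upper(k, K, n, N),
            })
    result = pd.DataFrame(rows)
    if result.empty:
        return pd.DataFrame(
            columns=["cluster", "term", "k", "K", "n", "N", "p_raw", "p_adj"]
        )
    result["p_adj"] = result.groupby("cluster")["p_raw"].transform(
        lambda p: adjust_bh(p.to_numpy())
    )
    return result.sort_values("p_raw", kind="mergesort").reset_index(drop=True)
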