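"""Gene-set over-representation analysis with -ln(p) enrichment scores.

For a query gene list (e.g. isoform-switch genes) against category
annotations, the over-representation p-value is the hypergeometric upper
tail P(X >= k) with k the query/category overlap, K the category size, n
the query size and N the universe size (equivalently a one-sided Fisher
exact test).  The enrichment score is -ln(p), the convention used by
common commercial analysis platforms, and categories are corrected across
tests with Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats

from .isoform_switch import fdr_step_up


@dataclass(frozen=True)
class AnnotationMap:
    """Category -> gene-set mapping over a gene universe."""

    categories: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError("annotation has no categories")
        stray = set().union(*self.categories.values()) - self.universe
        if stray:
            raise ValueError(f"{len(stray)} category genes outside the universe")


def read_annotation_tsv(path: str | Path, universe: set[str] | None = None) -> AnnotationMap:
    """Two-column TSV (category_id, gene_id); universe defaults to all annotated genes."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cats = {
        str(cat): frozenset(sub["gene_id"].astype(str))
        for cat, sub in df.groupby("category_id")
    }
    if universe is None:
        universe = set().union(*cats.values())
    return AnnotationMap(categories=cats, universe=frozenset(universe))


def write_annotation_tsv(annotation: AnnotationMap, path: str | Path) -> None:
    rows = [
        {"category_id": cat, "gene_id": g}
        for cat in sorted(annotation.categories)
        for g in sorted(annotation.categories[cat])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def overrepresentation_p(k: int, K: int, n: int, N: int) -> float:
    """Hypergeometric upper tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent margins k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_score(p_value: float) -> float:
    """-ln(p); the score is 0 at p = 1 and grows with significance."""
    if p_value <= 0:
        raise ValueError("p-value must be positive")
    return -math.log(p_value)


def enrich(query: set[str], annotation: AnnotationMap) -> pd.DataFrame:
    """Over-representation table (k, K, n, N, p, score, FDR) sorted by p.

    Query genes outside the universe are dropped with a warning; an empty
    query (after dropping) is an error.
    """
    query = set(query)
    outside = query - annotation.universe
    if outside:
        warnings.warn(f"dropping {len(outside)} query genes outside the universe", stacklevel=2)
        query -= outside
    if not query:
        raise ValueError("query is empty (or entirely outside the universe)")
    N = len(annotation.universe)
    n = len(query)
    rows = []
    for cat in sorted(annotation.categories):
        members = annotation.categories[cat]
        k = len(query & members)
        p = overrepresentation_p(k, len(members), n, N)
        rows.append({"category": cat, "k": k, "K": len(members), "n": n, "N": N,
                     "p_value": p, "enrichment_score": enrichment_score(p)})
    df = pd.DataFrame(rows)
    df["fdr"] = fdr_step_up(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "category"], kind="mergesort").reset_index(drop=True)
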