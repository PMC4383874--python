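"""Term-enrichment statistics for gene sets against annotation catalogs.

A catalog (pathway-, tissue- or disease-shaped) maps terms to member genes
over an annotated background.  Over-representation of a query gene set in a
term is tested with the hypergeometric upper tail (one-sided Fisher test),
with Benjamini-Hochberg control of the false discovery rate across the
catalog's terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class AnnotationCatalog:
    """Term -> member genes plus the background universe.

    When no explicit background is given it defaults to the union of all
    annotated genes (conservative: only annotated genes can score).
    """

    catalog_name: str
    term_members: Mapping[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        clean = {t: frozenset(m) for t, m in self.term_members.items()}
        object.__setattr__(self, "term_members", clean)
        for term, members in clean.items():
            if not members <= self.background:
                raise ValueError(f"term {term!r} has members outside the background")

    @classmethod
    def from_members(
        cls,
        catalog_name: str,
        term_members: Mapping[str, Iterable[str]],
        background: Iterable[str] | None = None,
    ) -> "AnnotationCatalog":
        tm = {t: frozenset(m) for t, m in term_members.items()}
        bg = frozenset(background) if background is not None else frozenset().union(*tm.values())
        return cls(catalog_name, tm, bg)

    @classmethod
    def from_tsv(cls, path: str | Path, catalog_name: str | None = None) -> "AnnotationCatalog":
        """Read 2-column TSV ``term_id<TAB>gene_id``."""
        members: dict[str, set[str]] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            term, gene = line.split("\t")[:2]
            members.setdefault(term.strip(), set()).add(gene.strip())
        return cls.from_members(catalog_name or Path(path).stem, members)


@dataclass(frozen=True)
class EnrichmentResult:
    """Rows: term_id, k (overlap), K (term size), n (query), N (background),
    p_value, fdr — sorted by p ascending, ties broken by term_id."""

    rows: pd.DataFrame
    dropped_genes: int = 0

    def to_tsv(self, path: str | Path) -> None:
        self.rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background size, K the term size, n the query size and k the
    observed overlap.  Computed via the log survival function for stability.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); exponentiate the log-sf for small tails
    return float(np.exp(hypergeom.logsf(k - 1, N, K, n)))


def bh_adjust(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out.tolist()


def enrich(query: Iterable[str], catalog: AnnotationCatalog) -> EnrichmentResult:
    """Hypergeometric over-representation of a query set per catalog term.

    Query genes outside the background are dropped (their count is reported).
    Every term with nonzero potential overlap is tested, and FDR is
    controlled across all tested terms of the catalog.
    """
    query_set = set(query)
    effective = query_set & catalog.background
    dropped = len(query_set) - len(effective)
    if not effective:
        raise ValueError("query has no genes in the catalog background")
    N = len(catalog.background)
    n = len(effective)
    records = []
    for term, members in catalog.term_members.items():
        K = len(members)
        if K == 0:
            continue
        k = len(effective & members)
        records.append((term, k, K, n, N, hypergeom_pvalue(k, K, n, N)))
    rows = pd.DataFrame(records, columns=["term_id", "k", "K", "n", "N", "p_value"])
    rows["fdr"] = bh_adjust(rows["p_value"])
    rows = rows.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(rows=rows, dropped_genes=dropped)
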