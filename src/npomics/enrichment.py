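"""Over-representation analysis of gene lists against GMT annotation sets.

Significance is the hypergeometric upper tail: for a query of size ``n``
drawn from a universe of size ``N``, the probability of seeing at least the
observed overlap ``k`` with a term of size ``K``. One-sided
over-representation only, Benjamini-Hochberg correction across the terms of
one annotation source, and fold enrichment ``(k/n)/(K/N)`` as the effect
size. The universe is whatever was measured, not the whole genome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .exceptions import ValidationError

RESULT_COLUMNS = ["term_id", "description", "k", "n", "K", "N", "p", "q", "fold_enrichment"]


@dataclass
class AnnotationSet:
    """Named gene sets over a measured universe.

    ``terms`` maps term id to ``(description, gene set)``. Every term must
    be a non-empty subset of ``universe``.
    """

    terms: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)
    universe: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValidationError(f"term {term_id!r} is empty")
            stray = genes - self.universe
            if stray:
                raise ValidationError(
                    f"term {term_id!r} contains genes outside the universe: {sorted(stray)[:5]}"
                )


def read_gmt(path, universe=None) -> AnnotationSet:
    """Read a GMT file (term, description, then member genes, tab-separated).

    If ``universe`` is not given it defaults to the union of all term genes.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
        term_id, description, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term_id in terms:
            raise ValidationError(f"{path}:{lineno}: duplicate term id {term_id!r}")
        terms[term_id] = (description, frozenset(genes))
    if universe is None:
        universe = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
    return AnnotationSet(terms=terms, universe=frozenset(universe))


def write_gmt(annotation: AnnotationSet, path) -> None:
    lines = []
    for term_id in sorted(annotation.terms):
        description, genes = annotation.terms[term_id]
        lines.append("\t".join([term_id, description, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def enrich(query, annotation: AnnotationSet) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term.

    Query genes outside the universe are dropped with a warning (their
    count is recorded in ``result.attrs["n_dropped"]``). Returns one row per
    term sorted by p ascending, with BH q-values across all terms.
    """
    from .diffexpr import bh_adjust  # local import to avoid a cycle at import time

    query = set(query)
    stray = query - annotation.universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe were dropped", stacklevel=2
        )
    query &= annotation.universe
    if not query:
        raise ValidationError("query is empty after restricting to the universe")
    N, n = len(annotation.universe), len(query)
    rows = []
    for term_id, (description, genes) in annotation.terms.items():
        K = len(genes)
        k = len(query & genes)
        # P(X >= k), X ~ Hypergeom(N, K, n)
        p = float(hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N)
        rows.append((term_id, description, k, n, K, N, min(p, 1.0), fold))
    result = pd.DataFrame(
        rows, columns=["term_id", "description", "k", "n", "K", "N", "p", "fold_enrichment"]
    )
    result["q"] = bh_adjust(result["p"].to_numpy())
    result = result[RESULT_COLUMNS].sort_values(["p", "term_id"], kind="stable")
    result = result.reset_index(drop=True)
    result.attrs["n_dropped"] = len(stray)
    return result


def enrichment_report(results: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Rows with q below the threshold, in EnrichmentResult column order."""
    return results.loc[results["q"] < q_threshold, RESULT_COLUMNS].reset_index(drop=True)
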