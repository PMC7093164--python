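"""Local over-representation analysis and function-set comparison.

Replaces an external annotation web platform: a one-sided hypergeometric test
with Benjamini-Hochberg correction defines each gene set's "functions", and
per-seed function sets are compared between groups through the Function
Retention Index (FRI) and Function Acquisition Index (FAI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

if TYPE_CHECKING:  # pragma: no cover
    from genecoord.coordination import GeneSet
    from genecoord.io import AnalysisConfig

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCollection:
    """Term-to-gene-set annotation with per-term descriptions."""

    terms: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = sorted(t for t, genes in self.terms.items() if not genes)
        if empty:
            logger.warning("dropping %d terms with empty gene sets: %s",
                           len(empty), empty[:5])
            for t in empty:
                del self.terms[t]

    @property
    def universe(self) -> set[str]:
        """Union of all annotated genes."""
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return out

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class EnrichmentResult:
    """One term's over-representation statistics for one query set."""

    term_id: str
    description: str
    k: int  # query genes in the term
    K: int  # term size within the background
    n: int  # query size
    N: int  # background size
    p: float  # upper-tail hypergeometric probability of >= k hits
    q: float = float("nan")  # Benjamini-Hochberg adjusted p
    significant: bool = False


@dataclass
class FunctionComparison:
    """Per-seed-gene comparison of reference vs condition function sets.

    ``fri`` (retention) and ``fai`` (acquisition) are the fractions of the
    condition group's functions that are shared with, respectively absent
    from, the reference group; both are None when the condition set is empty.
    """

    seed_gene: str
    terms_ref: frozenset[str]
    terms_cond: frozenset[str]

    @property
    def common(self) -> frozenset[str]:
        return self.terms_ref & self.terms_cond

    @property
    def acquired(self) -> frozenset[str]:
        return self.terms_cond - self.terms_ref

    @property
    def lost(self) -> frozenset[str]:
        return self.terms_ref - self.terms_cond

    @property
    def fri(self) -> float | None:
        if not self.terms_cond:
            return None
        return len(self.common) / len(self.terms_cond)

    @property
    def fai(self) -> float | None:
        if not self.terms_cond:
            return None
        return len(self.acquired) / len(self.terms_cond)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeom(N, K, n).

    The p-value convention used by :func:`overrepresentation`: the chance of
    drawing at least ``k`` annotated genes when sampling ``n`` genes without
    replacement from a background of ``N`` containing ``K`` annotated ones.
    """
    if not 0 <= K <= N or not 0 <= n <= N:
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def overrepresentation(
    query: "GeneSet | Iterable[str]",
    background: Iterable[str],
    annotation: AnnotationCollection,
    config: "AnalysisConfig",
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` within ``background``.

    Each term is first intersected with the background; terms smaller than
    ``config.min_term_size`` after intersection are not tested. P-values are
    the exact upper-tail probability of observing at least ``k`` query genes
    in the term; q-values are Benjamini-Hochberg over the tested terms, and
    terms with ``q < config.fdr_alpha`` are flagged significant (the query's
    "functions" set). Results are sorted by (p, term_id).
    """
    query_genes = set(getattr(query, "gene_ids", query))
    bg = set(background)
    if not query_genes:
        logger.warning("empty query gene set; no terms tested")
        return []
    extra = query_genes - bg
    if extra:
        raise ValueError(
            f"query contains {len(extra)} genes outside the background, "
            f"e.g. {sorted(extra)[:3]}"
        )
    if not (bg & annotation.universe):
        raise ValueError("background shares no genes with the annotation universe")

    N, n = len(bg), len(query_genes)
    results: list[EnrichmentResult] = []
    for term_id in sorted(annotation.terms):
        term_bg = annotation.terms[term_id] & bg
        K = len(term_bg)
        if K < config.min_term_size:
            continue
        k = len(term_bg & query_genes)
        results.append(
            EnrichmentResult(
                term_id=term_id,
                description=annotation.descriptions.get(term_id, ""),
                k=k, K=K, n=n, N=N, p=hypergeom_tail(k, N, K, n),
            )
        )
    if results:
        _, qvals, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, q in zip(results, qvals):
            r.q = float(q)
            r.significant = bool(r.q < config.fdr_alpha)
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def significant_terms(results: Sequence[EnrichmentResult]) -> frozenset[str]:
    """The query's "functions": term ids with q below the FDR threshold."""
    return frozenset(r.term_id for r in results if r.significant)


def compare_functions(
    seed_gene: str,
    terms_ref: Iterable[str],
    terms_cond: Iterable[str],
) -> FunctionComparison:
    """Build the FRI/FAI comparison of two per-group function sets."""
    return FunctionComparison(
        seed_gene=seed_gene,
        terms_ref=frozenset(terms_ref),
        terms_cond=frozenset(terms_cond),
    )


def common_terms_across_seeds(
    comparisons: Sequence[FunctionComparison],
    group: str,
    annotation: AnnotationCollection | None = None,
) -> list[tuple[str, str]]:
    """Intersection of one group's function sets across all seed genes.

    ``group`` is ``"ref"`` or ``"cond"``. Returns sorted (term_id,
    description) pairs; descriptions are empty strings when no annotation is
    supplied.
    """
    if group not in ("ref", "cond"):
        raise ValueError(f"group must be 'ref' or 'cond', got {group!r}")
    if not comparisons:
        raise ValueError("at least one comparison is required")
    sets = [
        c.terms_ref if group == "ref" else c.terms_cond for c in comparisons
    ]
    common = frozenset.intersection(*sets)
    desc = annotation.descriptions if annotation is not None else {}
    return [(t, desc.get(t, "")) for t in sorted(common)]
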