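"""Fisher's-exact over-representation of a query gene list in named sets.

For a background ("universe") of N genes, a set with K members in the
background and a query of n genes overlapping the set in x genes, the
enrichment p-value is the hypergeometric upper tail P(X >= x).  Results
carry a Benjamini-Hochberg q-value and the Jaccard similarity

    J = overlap / (set_size + query_size - overlap).

Two sizing modes exist for Jaccard: ``restricted`` (sizes counted inside
the background; pipeline default) and whatever raw sizes a caller feeds
``jaccard`` directly, which is how published set sizes are reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    go_id: str
    set_size: int
    query_size: int
    overlap: int
    p_value: float
    jaccard: float
    q_value: float = float("nan")
    passes_fdr: bool = False
    overlap_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.overlap <= min(self.set_size, self.query_size):
            raise ValueError("overlap exceeds set or query size")
        if not 0.0 <= self.jaccard <= 1.0:
            raise ValueError("Jaccard outside [0, 1]")


def jaccard(set_size: int, query_size: int, overlap: int) -> float:
    """Jaccard similarity from the three counts; 0/0 is 0 by convention."""
    if overlap > min(set_size, query_size):
        raise ValueError(
            f"overlap {overlap} exceeds min(set_size={set_size}, "
            f"query_size={query_size})"
        )
    union = set_size + query_size - overlap
    return 0.0 if union == 0 else overlap / union


def fisher_pvalue(N: int, K: int, n: int, x: int) -> float:
    """Hypergeometric upper tail P(X >= x) with population N, K successes,
    n draws -- the one-sided Fisher's exact enrichment p."""
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrich(
    query: Iterable[str],
    sets: GeneSetCollection,
    universe: Iterable[str] | None = None,
    *,
    fdr_q: float = 0.05,
) -> list[EnrichmentResult]:
    """Enrichment of ``query`` in every set of ``sets``.

    The background defaults to the collection's declared universe, else
    the union of all sets.  Query genes outside the background are
    dropped with a warning.  One result per set, sorted by (p, name),
    with BH q-values and a pass/fail flag at FDR level ``fdr_q``.
    """
    background = frozenset(universe) if universe is not None else sets.background()
    if not background:
        raise ValueError("empty universe")
    query_set = set(query)
    stray = query_set - background
    if stray:
        logger.warning(
            "%d query genes outside the universe dropped: %s",
            len(stray), sorted(stray)[:5],
        )
        query_set -= stray
    N = len(background)
    n = len(query_set)
    results = []
    for name, members in sets.sets.items():
        inside = members & background
        overlap_genes = inside & query_set
        K, x = len(inside), len(overlap_genes)
        desc = sets.descriptions.get(name, "")
        results.append(
            EnrichmentResult(
                set_name=name,
                go_id=desc,
                set_size=K,
                query_size=n,
                overlap=x,
                p_value=fisher_pvalue(N, K, n, x),
                jaccard=jaccard(K, n, x),
                overlap_genes=frozenset(overlap_genes),
            )
        )
    if results:
        qs = bh_fdr([r.p_value for r in results])
        results = [
            replace(r, q_value=float(q), passes_fdr=bool(q <= fdr_q))
            for r, q in zip(results, qs)
        ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


def filter_and_rank(
    results: Sequence[EnrichmentResult],
    p_threshold: float | None = None,
    top_k: int | None = None,
) -> list[EnrichmentResult]:
    """Keep p < threshold, sort by (p, name), truncate to ``top_k``."""
    kept = [
        r for r in results if p_threshold is None or r.p_value < p_threshold
    ]
    kept.sort(key=lambda r: (r.p_value, r.set_name))
    return kept[:top_k] if top_k is not None else kept


def genes_covered(
    results: Sequence[EnrichmentResult], query: Iterable[str]
) -> int:
    """Number of query genes appearing in at least one surviving set."""
    query_set = set(query)
    covered: set[str] = set()
    for r in results:
        covered |= r.overlap_genes & query_set
    return len(covered)


def results_to_rows(results: Sequence[EnrichmentResult]) -> list[dict]:
    """Rows in the published-table layout (name, accession, sizes, stats)."""
    return [
        {
            "name": r.set_name,
            "go_id": r.go_id,
            "n_entities": r.set_size,
            "overlap": r.overlap,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "passes_fdr_q": r.passes_fdr,
            "jaccard": r.jaccard,
        }
        for r in results
    ]
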