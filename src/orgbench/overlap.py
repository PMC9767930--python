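"""Gene-set overlap statistics and GO term enrichment.

Overlap significance is the hypergeometric upper tail ``P[X >= k]`` on the
2x2 table against a stated gene universe; odds ratios with a zero cell are
reported as ``inf`` (and always pass an odds-ratio floor).

The GO enrichment offers the classic Fisher/hypergeometric test plus an
optional ``elim`` decorrelation: terms are processed leaves-to-root over a
child->parent DAG and genes of significant terms are removed from their
ancestors before those are tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = ["OverlapResult", "fisher_overlap", "overlap_matrix", "go_enrichment"]


@dataclass(frozen=True)
class OverlapResult:
    """Overlap of two gene sets within a universe."""

    set_a: str
    set_b: str
    universe_size: int
    size_a: int
    size_b: int
    overlap: int
    odds_ratio: float
    p: float


def fisher_overlap(
    a: set[str], b: set[str], universe: set[str], name_a: str = "A", name_b: str = "B"
) -> OverlapResult:
    """Hypergeometric overlap test of ``a`` and ``b`` within ``universe``.

    The 2x2 table is ``(k, |A|-k, |B|-k, N-|A|-|B|+k)`` and the odds ratio
    ``k*(N-|A|-|B|+k) / ((|A|-k)*(|B|-k))``; ``p = P[X >= k]`` for
    hypergeometric X with N draws parameters (N, |A|, |B|).
    """
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be contained in the universe")
    n = len(universe)
    k = len(a & b)
    na, nb = len(a), len(b)
    num = k * (n - na - nb + k)
    den = (na - k) * (nb - k)
    odds_ratio = float("inf") if den == 0 else num / den
    p = float(hypergeom.sf(k - 1, n, na, nb))
    return OverlapResult(name_a, name_b, n, na, nb, k, odds_ratio, min(p, 1.0))


def overlap_matrix(
    sets_a: dict[str, set[str]],
    sets_b: dict[str, set[str]],
    universe: set[str],
    or_min: float = 3.0,
    p_max: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All pairwise overlaps between two named-set collections.

    Returns ``(long_table, significance_mask)``: the long table keeps every
    raw value; the mask (rows = sets_a, columns = sets_b) is True where
    ``OR > or_min`` and ``p < p_max``.
    """
    rows = []
    mask = pd.DataFrame(False, index=list(sets_a), columns=list(sets_b))
    for name_a, a in sets_a.items():
        if not a:
            raise ValueError(f"empty set {name_a!r}")
        for name_b, b in sets_b.items():
            if not b:
                raise ValueError(f"empty set {name_b!r}")
            res = fisher_overlap(a, b, universe, name_a, name_b)
            significant = res.odds_ratio > or_min and res.p < p_max
            mask.loc[name_a, name_b] = significant
            rows.append(
                {
                    "set_a": name_a,
                    "set_b": name_b,
                    "universe": res.universe_size,
                    "size_a": res.size_a,
                    "size_b": res.size_b,
                    "overlap": res.overlap,
                    "odds_ratio": res.odds_ratio,
                    "p": res.p,
                    "significant": significant,
                }
            )
    return pd.DataFrame(rows), mask


def _topological_order(terms: set[str], dag: dict[str, set[str]]) -> list[str]:
    """Leaves-to-root order: every term before any of its ancestors."""
    children: dict[str, set[str]] = {t: set() for t in terms}
    indeg = {t: 0 for t in terms}
    for child, parents in dag.items():
        if child not in terms:
            continue
        for parent in parents & terms:
            children[parent].add(child)
            indeg[child] += 0  # counted via pending below
    # a term can be tested once all of its descendants are processed
    pending = {t: len(children[t]) for t in terms}
    ready = sorted(t for t in terms if pending[t] == 0)
    order: list[str] = []
    parents_of = {t: (dag.get(t, set()) & terms) for t in terms}
    while ready:
        term = ready.pop(0)
        order.append(term)
        for parent in sorted(parents_of[term]):
            pending[parent] -= 1
            if pending[parent] == 0:
                ready.append(parent)
        ready.sort()
    if len(order) != len(terms):
        raise ValueError("annotation DAG contains a cycle")
    return order


def go_enrichment(
    genes: set[str],
    universe: set[str],
    annotation: dict[str, set[str]],
    min_term_size: int = 15,
    method: str = "classic",
    dag: dict[str, set[str]] | None = None,
    elim_p: float = 0.01,
) -> pd.DataFrame:
    """Term enrichment of ``genes`` within ``universe``.

    ``annotation`` maps gene -> terms and is restricted to the universe.
    ``enrichment = (k/|genes|) / (|term|/|universe|)``; p is the
    hypergeometric upper tail.  ``method="elim"`` requires ``dag``
    (child -> parents): significant terms (p < ``elim_p``) have their genes
    removed from all ancestors before the ancestors are tested.
    """
    if method not in ("classic", "elim"):
        raise ValueError("method must be 'classic' or 'elim'")
    if method == "elim" and dag is None:
        raise ValueError("method='elim' requires a parent-child DAG")
    genes = genes & universe
    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene not in universe:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)
    term_genes = {t: g for t, g in term_genes.items() if len(g) >= min_term_size}

    if method == "elim":
        order = _topological_order(set(term_genes), dag)
        ancestors_cache: dict[str, set[str]] = {}

        def ancestors(term: str) -> set[str]:
            if term not in ancestors_cache:
                acc: set[str] = set()
                stack = list(dag.get(term, set()))
                while stack:
                    parent = stack.pop()
                    if parent not in acc:
                        acc.add(parent)
                        stack.extend(dag.get(parent, set()))
                ancestors_cache[term] = acc
            return ancestors_cache[term]
    else:
        order = sorted(term_genes)

    n_universe = len(universe)
    n_genes = len(genes)
    removed: dict[str, set[str]] = {t: set() for t in term_genes}
    rows = []
    for term in order:
        members = term_genes[term] - removed[term]
        k = len(members & genes)
        term_size = len(members)
        expected = n_genes * term_size / n_universe
        enr = (k / n_genes) / (term_size / n_universe) if n_genes and term_size else 0.0
        p = float(hypergeom.sf(k - 1, n_universe, term_size, n_genes))
        rows.append(
            {"term": term, "overlap": k, "term_size": term_size,
             "expected": expected, "enrichment": enr, "p": min(p, 1.0)}
        )
        if method == "elim" and p < elim_p:
            for anc in ancestors(term):
                if anc in removed:
                    removed[anc] |= members
    out = pd.DataFrame(rows).sort_values(["p", "term"]).reset_index(drop=True)
    return out
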