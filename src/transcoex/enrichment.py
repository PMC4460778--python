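"""Annotation-term enrichment of gene sets and category-level comparison.

Per-set enrichment is the upper-tail hypergeometric test of the overlap
between a gene set and each annotation term, against a background
universe (by default the genes measured in the merged matrix, not the
whole genome), with Benjamini-Hochberg correction across the terms of
one set.  Enriched terms are then folded into representative categories
and the shared and disease-specific groups of gene sets are compared by
their normalized per-category counts and fold ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .refinement import bh_correct


class InputError(ValueError):
    pass


@dataclass
class AnnotationSet:
    """Term id -> (term name, gene set), plus the background universe."""

    terms: dict[str, tuple[str, set[str]]]
    background: set[str]

    def __post_init__(self) -> None:
        if not self.background:
            raise InputError("background universe is empty")
        for tid, (_, genes) in self.terms.items():
            extra = genes - self.background
            if extra:
                raise InputError(
                    f"term {tid} has genes outside the background: {sorted(extra)[:5]}"
                )


def read_gmt(path, background: set[str] | None = None) -> AnnotationSet:
    """Load a GMT file (term, description, genes...) as an AnnotationSet.

    Without an explicit background the union of all term genes is used;
    with one, term gene sets are clipped to it.
    """
    terms: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            genes = {g for g in parts[2:] if g}
            terms[parts[0]] = (parts[1], genes)
    if background is None:
        background = set().union(*(g for _, g in terms.values())) if terms else set()
    else:
        terms = {t: (n, g & background) for t, (n, g) in terms.items()}
    return AnnotationSet(terms, set(background))


def read_category_map(path) -> dict[str, str]:
    """Two-column TSV (term_id, category) -> mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["term_id", "category"]
    return dict(zip(df["term_id"], df["category"]))


# ---------------------------------------------------------------------------
# hypergeometric test


def hypergeom_pvalue(universe: int, term: int, drawn: int, overlap: int) -> float:
    """P(X >= overlap) for X hypergeometric(universe, term, drawn)."""
    return float(hypergeom.sf(overlap - 1, universe, term, drawn))


def hypergeom_pvalue_enumerated(
    universe: int, term: int, drawn: int, overlap: int
) -> float:
    """Same tail by direct enumeration (small-universe oracle)."""
    total = math.comb(universe, drawn)
    acc = 0
    for k in range(overlap, min(term, drawn) + 1):
        acc += math.comb(term, k) * math.comb(universe - term, drawn - k)
    return acc / total


def hypergeom_enrich(
    gene_set, annotation: AnnotationSet, alpha: float = 0.005
) -> list[tuple[str, str, float, float]]:
    """Terms enriched in a gene set at BH-corrected q <= alpha.

    Returns (term id, term name, p, q) sorted by q then term id.  The
    gene set is intersected with the background first.
    """
    genes = set(gene_set) & annotation.background
    if not genes:
        raise InputError("gene set does not intersect the background universe")
    universe = len(annotation.background)
    drawn = len(genes)
    term_ids = sorted(annotation.terms)
    ps = []
    for tid in term_ids:
        _, term_genes = annotation.terms[tid]
        overlap = len(genes & term_genes)
        ps.append(hypergeom_pvalue(universe, len(term_genes), drawn, overlap))
    qs = bh_correct(ps)
    hits = [
        (tid, annotation.terms[tid][0], p, q)
        for tid, p, q in zip(term_ids, ps, qs)
        if q <= alpha
    ]
    return sorted(hits, key=lambda h: (h[3], h[0]))


# ---------------------------------------------------------------------------
# category profiles


def category_profile(
    sets_with_enrichment: list[list[tuple]], category_map: dict[str, str]
) -> pd.DataFrame:
    """Per-category counts of gene sets, normalized by the number of
    sets with >= 1 enriched term.

    ``sets_with_enrichment`` holds one enriched-term list (as returned by
    :func:`hypergeom_enrich`) per gene set.  A set counts once for every
    category containing at least one of its enriched terms, so fractions
    can sum to more than 1 across categories.
    """
    n_enriched_sets = sum(1 for hits in sets_with_enrichment if hits)
    counts: dict[str, int] = {}
    for hits in sets_with_enrichment:
        cats = {category_map[tid] for tid, *_ in hits if tid in category_map}
        for c in cats:
            counts[c] = counts.get(c, 0) + 1
    rows = [
        (c, n, n / n_enriched_sets if n_enriched_sets else 0.0)
        for c, n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["category", "count", "fraction"])


def fold_comparison(
    shared_profile: pd.DataFrame, specific_profile: pd.DataFrame
) -> pd.DataFrame:
    """Per-category ratio of shared over specific normalized fractions.

    Categories absent from a profile count as fraction 0; a category
    with specific fraction 0 gets an infinite fold and sorts last.
    """
    shared = dict(zip(shared_profile["category"], shared_profile["fraction"]))
    specific = dict(zip(specific_profile["category"], specific_profile["fraction"]))
    cats = sorted(set(shared) | set(specific))
    rows = []
    for c in cats:
        s, p = shared.get(c, 0.0), specific.get(c, 0.0)
        fold = math.inf if p == 0 else s / p
        rows.append((c, s, p, fold))
    rows.sort(key=lambda r: (math.isinf(r[3]), -r[3] if not math.isinf(r[3]) else 0, r[0]))
    return pd.DataFrame(
        rows, columns=["category", "shared_fraction", "specific_fraction", "fold"]
    )
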