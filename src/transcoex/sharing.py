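"""Summaries of how refined gene sets are shared across diseases.

Covers the descriptive layer of the analysis: the shared-vs-specific
partition of gene sets, pairwise disease sharing counts, the most
frequent genes per group, and annotation of genes with known
disease-gene lists either directly or through first-order neighbors in
a protein-interaction network.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

from .matrix import DISEASES
from .refinement import RefinedGeneSet


def partition_shared(
    sets: list[RefinedGeneSet],
) -> tuple[list[RefinedGeneSet], list[RefinedGeneSet]]:
    """Split into (shared: >= 2 diseases, specific: exactly 1 disease)."""
    shared = [s for s in sets if len(s.combination) >= 2]
    specific = [s for s in sets if len(s.combination) == 1]
    return shared, specific


def pairwise_counts(sets: list[RefinedGeneSet]) -> pd.DataFrame:
    """8x8 symmetric matrix of sharing counts.

    Off-diagonal (i, j): number of sets whose combination includes both
    diseases (the inclusive reading); diagonal: number of sets including
    disease i at all.
    """
    mat = pd.DataFrame(
        np.zeros((len(DISEASES), len(DISEASES)), dtype=int),
        index=DISEASES,
        columns=DISEASES,
    )
    for s in sets:
        members = sorted(s.combination)
        for i in members:
            for j in members:
                mat.loc[i, j] += 1
    return mat


def top_genes(
    sets: list[RefinedGeneSet], group: str = "shared", k: int = 30
) -> list[tuple[str, int]]:
    """Top-k genes by number of containing sets within a group.

    ``group`` is ``"shared"``, ``"specific"`` or ``"all"``; ties are
    broken lexicographically by gene id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    shared, specific = partition_shared(sets)
    pool = {"shared": shared, "specific": specific, "all": list(sets)}[group]
    counts: Counter[str] = Counter()
    for s in pool:
        counts.update(s.genes)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def read_disease_gene_tsv(path) -> dict[str, set[str]]:
    """TSV (disease, gene) -> mapping disease -> gene set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["disease", "gene"]
    out: dict[str, set[str]] = {}
    for d, g in zip(df["disease"], df["gene"]):
        out.setdefault(d, set()).add(g)
    unknown = set(out) - set(DISEASES)
    if unknown:
        raise ValueError(f"unknown disease labels in list: {sorted(unknown)}")
    return out


def read_edge_list_tsv(path) -> set[frozenset[str]]:
    """TSV (geneA, geneB) -> undirected edge set without self-loops."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["a", "b"]
    return {frozenset((a, b)) for a, b in zip(df["a"], df["b"]) if a != b}


def disease_gene_overlap(
    sets: list[RefinedGeneSet],
    disease_genes: dict[str, set[str]],
    network: set[frozenset[str]] | None = None,
) -> pd.DataFrame:
    """Per gene: diseases hit directly and via first-order interactors.

    ``direct`` lists diseases whose known gene list contains the gene;
    ``first_order`` lists diseases whose list intersects the gene's
    network neighbors.  One row per distinct gene over all sets.
    """
    neighbors: dict[str, set[str]] = {}
    for edge in network or ():
        a, b = sorted(edge)
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)

    genes = sorted({g for s in sets for g in s.genes})
    rows = []
    for g in genes:
        direct = sorted(d for d in DISEASES if g in disease_genes.get(d, set()))
        nb = neighbors.get(g, set())
        first = sorted(
            d for d in DISEASES if nb & disease_genes.get(d, set())
        )
        rows.append((g, ",".join(direct), ",".join(first)))
    return pd.DataFrame(rows, columns=["gene", "direct", "first_order"])
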