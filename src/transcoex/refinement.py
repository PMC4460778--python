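"""From raw biclusters to disease-combination gene sets with significance.

A bicluster is kept only when it contains *all* samples of at least one
disease class; samples of partially covered classes (including partially
covered controls) are trimmed away.  The surviving gene set is labelled
with its disease combination — the set of completely covered disease
classes — and scored by the difference in average pairwise Pearson
correlation (avg PCC) between the union of its diseases' samples and the
control samples.  Significance comes from an empirical null: the same
delta computed for many random gene groups of the same size over the
same disease-sample union, with an add-one two-sided p-value and
Benjamini-Hochberg correction applied jointly across all tested sets.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .biclic import Bicluster, avg_pcc
from .matrix import CONTROL, DISEASES, ExpressionMatrix


class PreconditionError(ValueError):
    pass


@dataclass(frozen=True)
class RefinedGeneSet:
    """A disease-combination gene set with its coexpression-change statistics."""

    genes: frozenset[str]
    combination: frozenset[str]
    pcc_disease: float
    pcc_normal: float
    delta: float
    p_value: float
    q_value: float

    @property
    def direction(self) -> str:
        return "gain" if self.delta > 0 else "loss"

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.combination)), tuple(sorted(self.genes)))


@dataclass(frozen=True)
class NullDistribution:
    """Sampled delta values for one (gene-set size, disease combination)."""

    set_size: int
    combination: frozenset[str]
    deltas: tuple[float, ...]
    n_draws: int
    seed: int

    def __post_init__(self) -> None:
        assert len(self.deltas) == self.n_draws


def validate_class_map(class_map: dict[str, set[str]]) -> None:
    seen: set[str] = set()
    for label, ids in class_map.items():
        if seen & ids:
            raise PreconditionError(f"class {label} overlaps another class")
        seen |= ids
    if not class_map.get(CONTROL):
        raise PreconditionError("control class is empty")


# ---------------------------------------------------------------------------
# selection


def select_and_trim(
    bicluster: Bicluster, class_map: dict[str, set[str]]
) -> tuple[frozenset[str], frozenset[str], frozenset[str]] | None:
    """Keep a bicluster only if it fully covers >= 1 disease class.

    Returns ``(genes, combination, refined samples)`` where the
    combination is the set of disease classes whose samples are all in
    the bicluster, and the refined sample set is the union of the
    completely covered classes' samples (partially covered classes,
    controls included, are trimmed).  Returns ``None`` when no disease
    class is complete; gene sets coexpressed only among controls are not
    assigned a combination — loss of coexpression surfaces instead as a
    disease-complete set with negative delta.
    """
    complete = [
        label
        for label in class_map
        if class_map[label] and class_map[label] <= bicluster.samples
    ]
    combination = frozenset(label for label in complete if label in DISEASES)
    if not combination:
        return None
    refined = frozenset().union(*(class_map[label] for label in complete))
    return bicluster.genes, combination, refined


# ---------------------------------------------------------------------------
# delta statistic


def _zscore_rows(block: np.ndarray) -> np.ndarray:
    mean = block.mean(axis=1, keepdims=True)
    centered = block - mean
    sd = np.sqrt((centered**2).mean(axis=1, keepdims=True))
    return np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)


def coexpression_delta(
    matrix: ExpressionMatrix,
    genes,
    combination,
    class_map: dict[str, set[str]],
) -> tuple[float, float, float]:
    """avg PCC over the combination's disease samples, over controls, and
    their difference (disease minus normal)."""
    genes = sorted(genes)
    if len(genes) < 2:
        raise PreconditionError("need at least 2 genes")
    disease_samples = sorted(
        set().union(*(class_map[c] for c in combination)) if combination else set()
    )
    normal_samples = sorted(class_map.get(CONTROL, set()))
    if len(disease_samples) < 3 or len(normal_samples) < 3:
        raise PreconditionError("need >= 3 samples on both sides")
    pcc_d = avg_pcc(matrix, genes, disease_samples)
    pcc_n = avg_pcc(matrix, genes, normal_samples)
    return pcc_d, pcc_n, pcc_d - pcc_n


# ---------------------------------------------------------------------------
# permutation null


def _null_seed(master_seed: int, set_size: int, combination) -> int:
    tag = f"{set_size}|{','.join(sorted(combination))}".encode()
    return (int(master_seed) * 1_000_003 + zlib.crc32(tag)) % (2**31)


def build_null(
    matrix: ExpressionMatrix,
    set_size: int,
    combination,
    class_map: dict[str, set[str]],
    n_draws: int = 100_000,
    seed: int = 0,
) -> NullDistribution:
    """Delta distribution of random same-size gene groups.

    ``n_draws`` gene groups of ``set_size`` genes are drawn uniformly
    without replacement from all genes of the matrix; each group's delta
    is computed exactly as :func:`coexpression_delta` with the same
    disease combination.  Deterministic for a fixed seed.
    """
    if set_size < 2:
        raise PreconditionError("set_size must be >= 2")
    if n_draws < 1:
        raise PreconditionError("n_draws must be >= 1")
    if set_size > matrix.n_genes:
        raise PreconditionError("set_size exceeds the number of genes")

    disease_samples = sorted(set().union(*(class_map[c] for c in combination)))
    normal_samples = sorted(class_map[CONTROL])
    X = matrix.values
    zd = _zscore_rows(X[disease_samples].to_numpy(dtype=float))
    zn = _zscore_rows(X[normal_samples].to_numpy(dtype=float))
    nd, nn = zd.shape[1], zn.shape[1]

    rng = np.random.default_rng(seed)
    n_genes = matrix.n_genes
    k = set_size
    deltas = np.empty(n_draws)
    chunk = max(
        1,
        min(n_draws, 4_000_000 // n_genes, 20_000_000 // (k * (nd + nn))),
    )
    pairs = k * (k - 1)
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        # uniform k-subsets: k smallest of a random row permutation key
        keys = rng.random((m, n_genes))
        idx = np.argpartition(keys, k, axis=1)[:, :k]
        # avg pairwise r of a group = (|sum of z rows|^2 / n - sum of r_gg) / (k(k-1))
        sd_sum = zd[idx].sum(axis=1)
        sn_sum = zn[idx].sum(axis=1)
        diag_d = (zd[idx] ** 2).sum(axis=(1, 2)) / nd
        diag_n = (zn[idx] ** 2).sum(axis=(1, 2)) / nn
        avg_d = ((sd_sum**2).sum(axis=1) / nd - diag_d) / pairs
        avg_n = ((sn_sum**2).sum(axis=1) / nn - diag_n) / pairs
        deltas[done : done + m] = avg_d - avg_n
        done += m
    return NullDistribution(
        set_size=k,
        combination=frozenset(combination),
        deltas=tuple(deltas.tolist()),
        n_draws=n_draws,
        seed=seed,
    )


def empirical_p(delta: float, null: NullDistribution) -> float:
    """Add-one two-sided empirical p-value of a delta against its null."""
    arr = np.abs(np.asarray(null.deltas))
    exceed = int((arr >= abs(delta) - 1e-15).sum())
    return (1 + exceed) / (null.n_draws + 1)


# ---------------------------------------------------------------------------
# multiple testing


def bh_correct(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise PreconditionError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


# ---------------------------------------------------------------------------
# driver


def refine_all(
    biclusters,
    matrix: ExpressionMatrix,
    class_map: dict[str, set[str]] | None = None,
    alpha: float = 0.005,
    n_draws: int = 100_000,
    seed: int = 0,
    null_cache: dict | None = None,
) -> list[RefinedGeneSet]:
    """Select, score and test all biclusters; keep sets with q <= alpha.

    Nulls are cached per (gene-set size, disease combination) with a seed
    derived from the master seed, so the result does not depend on the
    order in which biclusters arrive.  Identical (genes, combination)
    pairs arising from different biclusters are tested once.
    """
    if class_map is None:
        class_map = matrix.class_map()
    validate_class_map(class_map)
    cache = null_cache if null_cache is not None else {}

    tested: dict[tuple, tuple] = {}
    for b in sorted(biclusters, key=Bicluster.sort_key):
        sel = select_and_trim(b, class_map)
        if sel is None:
            continue
        genes, combination, _ = sel
        tested.setdefault((genes, combination), None)

    keys = sorted(tested, key=lambda k: (tuple(sorted(k[1])), tuple(sorted(k[0]))))
    records = []
    for genes, combination in keys:
        pcc_d, pcc_n, delta = coexpression_delta(matrix, genes, combination, class_map)
        ck = (len(genes), combination)
        if ck not in cache:
            cache[ck] = build_null(
                matrix,
                len(genes),
                combination,
                class_map,
                n_draws=n_draws,
                seed=_null_seed(seed, len(genes), combination),
            )
        p = empirical_p(delta, cache[ck])
        records.append((genes, combination, pcc_d, pcc_n, delta, p))

    qs = bh_correct([r[5] for r in records])
    out = [
        RefinedGeneSet(
            genes=r[0],
            combination=r[1],
            pcc_disease=r[2],
            pcc_normal=r[3],
            delta=r[4],
            p_value=r[5],
            q_value=q,
        )
        for r, q in zip(records, qs)
        if q <= alpha
    ]
    return sorted(out, key=RefinedGeneSet.sort_key)


# ---------------------------------------------------------------------------
# I/O


def refined_to_frame(sets: list[RefinedGeneSet]) -> pd.DataFrame:
    """Tabular form: one flag column per disease plus the statistics."""
    rows = []
    for s in sets:
        row = {d: int(d in s.combination) for d in DISEASES}
        row.update(
            pcc_disease=s.pcc_disease,
            pcc_normal=s.pcc_normal,
            delta=s.delta,
            p_value=s.p_value,
            q_value=s.q_value,
            direction=s.direction,
            genes=",".join(sorted(s.genes)),
        )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=list(DISEASES)
        + [
            "pcc_disease",
            "pcc_normal",
            "delta",
            "p_value",
            "q_value",
            "direction",
            "genes",
        ],
    )


def frame_to_refined(df: pd.DataFrame) -> list[RefinedGeneSet]:
    out = []
    for _, row in df.iterrows():
        out.append(
            RefinedGeneSet(
                genes=frozenset(str(row["genes"]).split(",")),
                combination=frozenset(d for d in DISEASES if int(row[d]) == 1),
                pcc_disease=float(row["pcc_disease"]),
                pcc_normal=float(row["pcc_normal"]),
                delta=float(row["delta"]),
                p_value=float(row["p_value"]),
                q_value=float(row["q_value"]),
            )
        )
    return out
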