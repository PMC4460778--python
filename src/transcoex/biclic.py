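"""Correlation-based biclustering of an expression matrix.

The algorithm searches for biclusters — gene subsets that are mutually
correlated over a sample subset — whose *average pairwise Pearson
correlation* (avg PCC) meets a threshold (default 0.7).  It proceeds in
four stages:

1. **Per-sample seeding.**  In every sample the genes are ordered by
   expression value and partitioned into small consecutive windows.
2. **Seed collection.**  A window's gene set becomes a seed bicluster
   together with every sample in which (nearly) the same gene set forms
   a window; seeds need at least ``min_samples`` supporting samples.
3. **Two-direction expansion.**  Each seed is expanded separately in the
   gene direction (over its samples) and the sample direction (over its
   genes), greedily adding the candidate that yields the highest avg PCC
   while the threshold holds; genes are capped at ``max_genes``, samples
   are uncapped.
4. **In-space optimization.**  Within the search space spanned by the two
   expansions, single genes — or, when no gene removal helps, single
   samples — are removed, always the one whose removal raises avg PCC
   most, stopping at the first state meeting the threshold.  Removing
   genes before samples maximizes the number of samples retained.

Expansion and optimization are iterated from each seed until a fixpoint,
so a seed polluted by a few unrelated genes can first be trimmed to its
correlated core and then regrown over all consistent samples.  Emitted
biclusters satisfy ``min_genes <= |genes| <= max_genes``,
``|samples| >= min_samples`` and ``avg_pcc >= pcc_threshold``; exact
duplicates and biclusters contained in another are dropped.

Ties are always broken lexicographically by gene or sample id, and the
whole procedure is deterministic for a fixed input and parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .matrix import ExpressionMatrix

_EPS = 1e-12


class PreconditionError(ValueError):
    pass


@dataclass(frozen=True)
class BiclicParams:
    """Tunable knobs of the bicluster search.

    ``pcc_threshold`` is the minimum average pairwise Pearson correlation
    of an emitted bicluster; 0.7 makes an arbitrary bicluster's chance of
    qualifying rare.  ``seed_window`` is the width of the per-sample rank
    windows used for seeding.  ``seed_span`` controls when another sample
    supports a seed window: its genes must all lie within
    ``seed_span * |window|`` consecutive rank positions (measured in whole
    windows) of that sample, i.e. they still cluster together even if the
    window boundaries shifted.  ``seed_span=None`` demands the identical
    gene set as a window, which only expression-rank-stable data can
    satisfy.
    """

    pcc_threshold: float = 0.7
    max_genes: int = 50
    min_genes: int = 2
    min_samples: int = 3
    seed_window: int = 5
    seed_span: float | None = 3.0

    def __post_init__(self) -> None:
        if not (0.0 < self.pcc_threshold <= 1.0):
            raise PreconditionError("pcc_threshold must be in (0, 1]")
        if self.min_genes < 2:
            raise PreconditionError("min_genes must be >= 2")
        if self.min_samples < 3:
            raise PreconditionError("min_samples must be >= 3 (PCC needs 3 points)")
        if self.max_genes < self.min_genes:
            raise PreconditionError("max_genes < min_genes")
        if self.seed_window < 2:
            raise PreconditionError("seed_window must be >= 2")
        if self.seed_span is not None and self.seed_span < 1.0:
            raise PreconditionError("seed_span must be >= 1 (or None for exact match)")


@dataclass(frozen=True)
class Bicluster:
    genes: frozenset[str]
    samples: frozenset[str]
    avg_pcc: float

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.genes)), tuple(sorted(self.samples)))

    def to_dict(self) -> dict:
        return {
            "genes": sorted(self.genes),
            "samples": sorted(self.samples),
            "avg_pcc": self.avg_pcc,
        }


# ---------------------------------------------------------------------------
# average pairwise Pearson correlation


def _corr_matrix(sub: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation; zero-variance rows correlate 0."""
    n = sub.shape[1]
    mean = sub.mean(axis=1, keepdims=True)
    centered = sub - mean
    sd = np.sqrt((centered**2).mean(axis=1, keepdims=True))
    safe = np.where(sd > 0, sd, 1.0)
    z = np.where(sd > 0, centered / safe, 0.0)
    return (z @ z.T) / n


def _avg_from_corr(r: np.ndarray) -> float:
    k = r.shape[0]
    return float((r.sum() - np.trace(r)) / (k * (k - 1)))


def avg_pcc(matrix: ExpressionMatrix, genes, samples) -> float:
    """Mean Pearson correlation over all unordered gene pairs.

    Correlations are computed across the given samples; a pair involving
    a zero-variance gene contributes 0.
    """
    genes, samples = sorted(genes), sorted(samples)
    if len(genes) < 2:
        raise PreconditionError("avg_pcc needs at least 2 genes")
    if len(samples) < 3:
        raise PreconditionError("avg_pcc needs at least 3 samples")
    sub = matrix.values.loc[genes, samples].to_numpy(dtype=float)
    return _avg_from_corr(_corr_matrix(sub))


# ---------------------------------------------------------------------------
# seeding


def sample_seed_clusters(
    matrix: ExpressionMatrix, sample_id: str, params: BiclicParams
) -> list[set[str]]:
    """Partition one sample's expression-ranked genes into seed windows.

    Genes are sorted by their value in the sample (value ties broken by
    gene id, so the grouping is deterministic) and cut into consecutive
    windows of ``seed_window`` genes; a smaller trailing window is kept
    only if it still has ``min_genes`` genes.
    """
    if sample_id not in matrix.values.columns:
        raise PreconditionError(f"unknown sample {sample_id!r}")
    col = matrix.values[sample_id]
    ordered = sorted(col.index, key=lambda g: (col[g], g))
    w = params.seed_window
    groups = [set(ordered[i : i + w]) for i in range(0, len(ordered), w)]
    if groups and len(groups[-1]) < params.min_genes:
        groups.pop()
    return groups


def find_seeds(
    per_sample_clusters: dict[str, list[set[str]]], params: BiclicParams
) -> list[Bicluster]:
    """Collect seed biclusters: windows co-clustered in >= min_samples samples.

    With ``seed_span=None`` a sample supports a window only when it
    contains the identical gene set as one of its own windows.  With a
    numeric ``seed_span``, a sample supports the window when all of the
    window's genes fall within a bounded stretch of its expression
    ranking — at most ``ceil(seed_span * |window| / seed_window)``
    consecutive windows — so the genes still cluster together there even
    though window boundaries drift under noise.  Seed ``avg_pcc`` is not
    yet computed (set to NaN); duplicate seeds are merged.
    """
    sample_ids = sorted(per_sample_clusters)
    if params.seed_span is None:
        incidence: dict[frozenset[str], set[str]] = {}
        for s in sample_ids:
            for cluster in per_sample_clusters[s]:
                incidence.setdefault(frozenset(cluster), set()).add(s)
        return [
            Bicluster(genes, frozenset(samples), float("nan"))
            for genes, samples in sorted(
                incidence.items(), key=lambda kv: tuple(sorted(kv[0]))
            )
            if len(samples) >= params.min_samples
        ]

    genes = sorted({g for s in sample_ids for c in per_sample_clusters[s] for g in c})
    g2i = {g: i for i, g in enumerate(genes)}
    n_s, n_g = len(sample_ids), len(genes)
    win_of = np.full((n_s, n_g), -1, dtype=np.int32)
    for si, s in enumerate(sample_ids):
        for wi, cluster in enumerate(per_sample_clusters[s]):
            for g in cluster:
                win_of[si, g2i[g]] = wi

    seeds: dict[frozenset[str], set[str]] = {}
    sample_arr = np.array(sample_ids)
    for s in sample_ids:
        for cluster in per_sample_clusters[s]:
            members = np.fromiter((g2i[g] for g in sorted(cluster)), dtype=np.int64)
            ws = len(members)
            max_windows = int(np.ceil(params.seed_span * ws / params.seed_window))
            sub = win_of[:, members]
            present = (sub >= 0).all(axis=1)
            span = sub.max(axis=1) - sub.min(axis=1) + 1
            support = sample_arr[present & (span <= max_windows)]
            if len(support) >= params.min_samples:
                seeds.setdefault(frozenset(cluster), set()).update(support)

    return [
        Bicluster(g, frozenset(s), float("nan"))
        for g, s in sorted(seeds.items(), key=lambda kv: tuple(sorted(kv[0])))
        if len(s) >= params.min_samples
    ]


# ---------------------------------------------------------------------------
# expansion


def expand_genes(
    matrix: ExpressionMatrix, seed: Bicluster, params: BiclicParams
) -> set[str]:
    """Greedy gene expansion over the seed's samples.

    Repeatedly adds the candidate gene with the highest mean correlation
    to the current gene set, as long as that mean correlation itself
    reaches the threshold and at most ``max_genes`` genes are used; every
    member of a coexpressed set must be coexpressed with the others, so a
    gene cannot buy its way in on the strength of the existing pairs.
    (By the mediant inequality the set's avg PCC then also stays at or
    above the threshold whenever it started there.)  Returns the expanded
    gene set (a superset of the seed's genes).
    """
    samples = sorted(seed.samples)
    gene_order = sorted(matrix.gene_ids)
    sub = matrix.values.loc[gene_order, samples].to_numpy(dtype=float)
    n = len(samples)
    mean = sub.mean(axis=1, keepdims=True)
    centered = sub - mean
    sd = np.sqrt((centered**2).mean(axis=1, keepdims=True))
    z = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)

    g2i = {g: i for i, g in enumerate(gene_order)}
    member = np.zeros(len(gene_order), dtype=bool)
    for g in seed.genes:
        member[g2i[g]] = True
    u = z[member].sum(axis=0)
    k = int(member.sum())
    r_seed = _corr_matrix(sub[member])
    pairsum = (r_seed.sum() - np.trace(r_seed)) / 2.0

    while k < params.max_genes:
        c = (z @ u) / n  # summed correlation of every gene to the members
        c[member] = -np.inf
        best = int(np.argmax(c))  # gene_order is lexicographic: first max wins
        if c[best] / k < params.pcc_threshold - _EPS:
            break
        member[best] = True
        pairsum += c[best]
        u = u + z[best]
        k += 1
    return {gene_order[i] for i in np.flatnonzero(member)}


class _SampleStats:
    """Incremental sufficient statistics of a gene set over a sample set.

    Tracks per-gene sums, sums of squares and the pairwise product matrix
    so that the avg PCC after adding or removing any candidate sample can
    be evaluated for all candidates at once.
    """

    def __init__(self, block: np.ndarray, active: np.ndarray):
        self.block = block  # genes x all-samples
        self.active = active.copy()  # bool over samples
        cur = block[:, active]
        self.n = int(active.sum())
        self.s1 = cur.sum(axis=1)
        self.s2 = (cur**2).sum(axis=1)
        self.pm = cur @ cur.T

    def _avg_from(self, n: int, s1, s2, pm) -> np.ndarray:
        # s1, s2: genes x m; pm: genes x genes x m
        num = n * pm - s1[:, None, :] * s1[None, :, :]
        var = np.maximum(n * s2 - s1**2, 0.0)
        den = np.sqrt(var[:, None, :] * var[None, :, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > _EPS, num / np.where(den > _EPS, den, 1.0), 0.0)
        k = s1.shape[0]
        diag = np.einsum("iim->m", r)
        return (r.sum(axis=(0, 1)) - diag) / (k * (k - 1))

    def eval_add(self, cand_idx: np.ndarray) -> np.ndarray:
        x = self.block[:, cand_idx]
        s1 = self.s1[:, None] + x
        s2 = self.s2[:, None] + x**2
        pm = self.pm[:, :, None] + x[:, None, :] * x[None, :, :]
        return self._avg_from(self.n + 1, s1, s2, pm)

    def eval_remove(self, cand_idx: np.ndarray) -> np.ndarray:
        x = self.block[:, cand_idx]
        s1 = self.s1[:, None] - x
        s2 = self.s2[:, None] - x**2
        pm = self.pm[:, :, None] - x[:, None, :] * x[None, :, :]
        return self._avg_from(self.n - 1, s1, s2, pm)

    def add(self, j: int) -> None:
        x = self.block[:, j]
        self.s1 += x
        self.s2 += x**2
        self.pm += np.outer(x, x)
        self.n += 1
        self.active[j] = True

    def remove(self, j: int) -> None:
        x = self.block[:, j]
        self.s1 -= x
        self.s2 -= x**2
        self.pm -= np.outer(x, x)
        self.n -= 1
        self.active[j] = False

    def current_avg(self) -> float:
        cur = self.block[:, self.active]
        return _avg_from_corr(_corr_matrix(cur))


def expand_samples(
    matrix: ExpressionMatrix, seed: Bicluster, params: BiclicParams
) -> set[str]:
    """Greedy sample expansion over the seed's genes (no sample cap)."""
    genes = sorted(seed.genes)
    sample_order = sorted(matrix.sample_ids)
    block = matrix.values.loc[genes, sample_order].to_numpy(dtype=float)
    s2i = {s: i for i, s in enumerate(sample_order)}
    active = np.zeros(len(sample_order), dtype=bool)
    for s in seed.samples:
        active[s2i[s]] = True

    stats = _SampleStats(block, active)
    while True:
        cand = np.flatnonzero(~stats.active)
        if len(cand) == 0:
            break
        avg = stats.eval_add(cand)
        best = int(np.argmax(avg))  # sample_order lexicographic: first max wins
        if avg[best] < params.pcc_threshold - _EPS:
            break
        stats.add(int(cand[best]))
    return {sample_order[i] for i in np.flatnonzero(stats.active)}


# ---------------------------------------------------------------------------
# optimization


def optimize_bicluster(
    matrix: ExpressionMatrix, gene_space, sample_space, params: BiclicParams
) -> Bicluster | None:
    """Shrink a search space to the first state meeting the threshold.

    Starting from the full ``gene_space`` x ``sample_space`` block, the
    single gene whose removal raises avg PCC most is removed; only when
    no gene removal raises it is a sample removal considered.  The search
    stops at the first state with avg PCC at or above the threshold
    (which may be the initial state).  Returns ``None`` when the minimum
    bicluster dimensions are reached without meeting the threshold.
    """
    genes = sorted(gene_space)
    samples = sorted(sample_space)
    if len(genes) < params.min_genes or len(samples) < params.min_samples:
        return None

    sample_order = samples[:]
    block_full = matrix.values.loc[genes, sample_order].to_numpy(dtype=float)
    gene_alive = np.ones(len(genes), dtype=bool)
    stats = _SampleStats(block_full, np.ones(len(sample_order), dtype=bool))

    def current_state():
        sub = block_full[gene_alive][:, stats.active]
        r = _corr_matrix(sub)
        return r, _avg_from_corr(r)

    r, avg = current_state()
    while avg < params.pcc_threshold - _EPS:
        k = int(gene_alive.sum())
        n_s = int(stats.active.sum())
        moved = False
        if k > params.min_genes:
            rowsum = r.sum(axis=1) - np.diag(r)
            pairsum = rowsum.sum() / 2.0
            new_avg = (pairsum - rowsum) / ((k - 1) * (k - 2) / 2.0)
            best = int(np.argmax(new_avg))
            if new_avg[best] > avg + _EPS:
                alive_idx = np.flatnonzero(gene_alive)
                gene_alive[alive_idx[best]] = False
                stats = _SampleStats(block_full[gene_alive], stats.active)
                r, avg = current_state()
                moved = True
        if not moved and n_s > params.min_samples:
            cand = np.flatnonzero(stats.active)
            avg_rm = stats.eval_remove(cand)
            best = int(np.argmax(avg_rm))
            if avg_rm[best] > avg + _EPS:
                stats.remove(int(cand[best]))
                r, avg = current_state()
                moved = True
        if not moved:
            return None

    out_genes = frozenset(g for g, a in zip(genes, gene_alive) if a)
    out_samples = frozenset(
        s for s, a in zip(sample_order, stats.active) if a
    )
    return Bicluster(out_genes, out_samples, avg)


# ---------------------------------------------------------------------------
# driver


def _refine_seed(
    matrix: ExpressionMatrix, seed: Bicluster, params: BiclicParams, max_rounds: int = 5
) -> Bicluster | None:
    state = seed
    seen: set[tuple] = set()
    result = None
    for _ in range(max_rounds):
        key = (state.genes, state.samples)
        if key in seen:
            break
        seen.add(key)
        gene_space = expand_genes(matrix, state, params)
        sample_space = expand_samples(matrix, state, params)
        opt = optimize_bicluster(matrix, gene_space, sample_space, params)
        if opt is None:
            return result
        if (opt.genes, opt.samples) == key:
            return opt
        state = opt
        result = opt
    return result


def run_biclic(
    matrix: ExpressionMatrix, params: BiclicParams | None = None
) -> list[Bicluster]:
    """Full bicluster search: seeds, expansion, optimization, dedup."""
    params = params or BiclicParams()
    clusters = {
        s: sample_seed_clusters(matrix, s, params) for s in matrix.sample_ids
    }
    seeds = find_seeds(clusters, params)

    found: dict[tuple, Bicluster] = {}
    for seed in seeds:
        result = _refine_seed(matrix, seed, params)
        if result is None:
            continue
        found[(result.genes, result.samples)] = result

    # drop biclusters strictly contained in another emitted bicluster
    items = sorted(found.values(), key=lambda b: (-len(b.genes), -len(b.samples)))
    kept: list[Bicluster] = []
    for b in items:
        contained = any(
            b.genes <= other.genes and b.samples <= other.samples for other in kept
        )
        if not contained:
            kept.append(b)

    for b in kept:
        assert params.min_genes <= len(b.genes) <= params.max_genes
        assert len(b.samples) >= params.min_samples
        assert b.avg_pcc >= params.pcc_threshold - 1e-9
    return sorted(kept, key=Bicluster.sort_key)


def exhaustive_biclusters(
    matrix: ExpressionMatrix, params: BiclicParams
) -> list[Bicluster]:
    """Brute-force enumeration of maximal qualifying blocks (test oracle).

    Only feasible on tiny matrices (<= ~8 genes and samples): every
    gene-subset x sample-subset block meeting the size and threshold
    constraints is scored, then non-maximal blocks are discarded.
    """
    genes = sorted(matrix.gene_ids)
    samples = sorted(matrix.sample_ids)
    if len(genes) > 10 or len(samples) > 10:
        raise PreconditionError("exhaustive search is a small-fixture oracle only")
    hits: list[Bicluster] = []
    for kg in range(params.min_genes, min(len(genes), params.max_genes) + 1):
        for gs in combinations(genes, kg):
            for ks in range(params.min_samples, len(samples) + 1):
                for ss in combinations(samples, ks):
                    a = avg_pcc(matrix, gs, ss)
                    if a >= params.pcc_threshold - _EPS:
                        hits.append(Bicluster(frozenset(gs), frozenset(ss), a))
    maximal = [
        b
        for b in hits
        if not any(
            (b.genes <= o.genes and b.samples <= o.samples and b != o) for o in hits
        )
    ]
    return sorted(maximal, key=Bicluster.sort_key)
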