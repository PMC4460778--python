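"""Merging heterogeneous expression datasets into one analysis matrix.

The merging stage mirrors the standard microarray-integration recipe:
per-dataset quantile normalization, collapsing probes to genes by
averaging, un-logging datasets stored on a log scale, intersecting gene
spaces, and removing residual cohort (batch) effects with a parametric
empirical-Bayes location/scale adjustment (the ComBat model: per-gene
standardization, normal prior on additive batch effects, inverse-gamma
prior on multiplicative ones, iterative shrinkage of both).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixError


class PreconditionError(ValueError):
    """An operation's input contract is violated."""


# ---------------------------------------------------------------------------
# un-log


def unlog_transform(matrix: ExpressionMatrix, base: float = 2.0) -> ExpressionMatrix:
    """Invert a log transform: every value v becomes ``base ** v``."""
    if base <= 0:
        raise PreconditionError("log base must be > 0")
    arr = matrix.values.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise PreconditionError("matrix contains non-finite values")
    return matrix.with_values(np.power(float(base), arr))


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the mean order-statistic profile.

    The reference profile is the row-wise mean of the per-column sorted
    values; ties within a column receive the mean of the reference values
    at their tied ranks.
    """
    arr = matrix.values.to_numpy(dtype=float)
    if arr.shape[1] < 2:
        raise PreconditionError("quantile normalization needs >= 2 samples")
    if np.isnan(arr).any():
        raise PreconditionError(
            "missing values present; filter incomplete probes first"
        )
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        sorted_col = col[order]
        # average the reference over tied runs
        boundaries = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        group_sums = np.add.reduceat(reference, boundaries)
        group_sizes = np.diff(np.r_[boundaries, n])
        tied_means = np.repeat(group_sums / group_sizes, group_sizes)
        assigned[order] = tied_means
        out[:, j] = assigned
    return matrix.with_values(out)


# ---------------------------------------------------------------------------
# probe collapsing


def read_probe_map(path) -> pd.Series:
    """Two-column TSV (probe_id, gene_id) -> Series probe -> gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = ["probe_id", "gene_id"]
    return df.set_index("probe_id")["gene_id"]


def collapse_probes(matrix: ExpressionMatrix, probe_map) -> ExpressionMatrix:
    """Average all probe rows mapping to the same gene id.

    ``probe_map`` maps probe id -> gene id (many-to-one); probes absent
    from the map are dropped.
    """
    probe_map = pd.Series(dict(probe_map)) if not isinstance(probe_map, pd.Series) else probe_map
    mapped = matrix.values.index.intersection(probe_map.index)
    if len(mapped) == 0:
        raise PreconditionError("no probe of the matrix appears in the probe map")
    sub = matrix.values.loc[mapped]
    genes = probe_map.loc[mapped]
    collapsed = sub.groupby(genes.to_numpy()).mean()
    collapsed.index.name = matrix.values.index.name
    return ExpressionMatrix(collapsed.sort_index(), matrix.sample_meta.copy())


# ---------------------------------------------------------------------------
# stacking


def intersect_and_stack(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Stack datasets over their common gene set (genes lexicographic)."""
    if len(matrices) < 2:
        raise PreconditionError("need at least 2 matrices to stack")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if len(common) < 2:
        raise PreconditionError("gene-id intersection has fewer than 2 genes")
    genes = sorted(common)
    all_samples: list[str] = []
    for m in matrices:
        all_samples.extend(m.sample_ids)
    if len(set(all_samples)) != len(all_samples):
        raise MatrixError("duplicate sample ids across input matrices")
    values = pd.concat([m.values.loc[genes] for m in matrices], axis=1)
    meta = pd.concat([m.sample_meta for m in matrices], axis=0)
    return ExpressionMatrix(values, meta)


# ---------------------------------------------------------------------------
# ComBat


def combat_adjust(
    matrix: ExpressionMatrix, conv: float = 1e-4, max_iter: int = 500
) -> ExpressionMatrix:
    """Parametric empirical-Bayes batch adjustment (location and scale).

    Per gene the data are standardized against the batch-size-weighted
    grand mean and pooled variance; batch-wise means (normal prior) and
    variances (inverse-gamma prior) are shrunk toward their across-gene
    priors by iterated conditional posterior means, then removed.  Class
    labels are deliberately withheld from the batch model so that the
    adjustment cannot absorb biological signal.

    Genes with zero overall variance cannot be standardized; they are
    passed through unadjusted with a warning.
    """
    meta = matrix.sample_meta
    batches = matrix.batches()
    if len(batches) < 2:
        raise PreconditionError("batch adjustment needs >= 2 batches")
    batch_of = meta.loc[matrix.sample_ids, "batch"].to_numpy()
    groups = [np.flatnonzero(batch_of == b) for b in batches]
    if any(len(g) < 2 for g in groups):
        raise PreconditionError("every batch needs >= 2 samples")

    X = matrix.values.to_numpy(dtype=float)
    n_genes, n_array = X.shape
    n_b = np.array([len(g) for g in groups], dtype=float)

    flat = X.var(axis=1) == 0.0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene(s) passed through unadjusted",
            stacklevel=2,
        )

    batch_means = np.column_stack([X[:, g].mean(axis=1) for g in groups])
    grand_mean = batch_means @ (n_b / n_array)
    fitted = np.empty_like(X)
    for g, idx in zip(groups, range(len(groups))):
        fitted[:, g] = batch_means[:, [idx]]
    var_pooled = ((X - fitted) ** 2).mean(axis=1)
    ok = ~flat & (var_pooled > 0)

    s_data = np.zeros_like(X)
    s_data[ok] = (X[ok] - grand_mean[ok, None]) / np.sqrt(var_pooled[ok, None])

    adjusted = X.copy()
    bayes = np.empty((ok.sum(), n_array))
    sub = s_data[ok]
    for bi, g in enumerate(groups):
        gamma_hat = sub[:, g].mean(axis=1)
        delta_hat = sub[:, g].var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
        a_prior = (2 * s2 + m**2) / s2
        b_prior = (m * s2 + m**3) / s2
        n = float(len(g))
        g_old, d_old = gamma_hat.copy(), delta_hat.copy()
        for _ in range(max_iter):
            g_new = (t2 * n * gamma_hat + d_old * gamma_bar) / (t2 * n + d_old)
            sum2 = ((sub[:, g] - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior) / (n / 2 + a_prior - 1)
            # convergence test mirrors the reference EB iteration exactly
            # (signed denominators), so fixpoints agree to float precision
            change = max(
                np.max(np.abs(g_new - g_old) / g_old),
                np.max(np.abs(d_new - d_old) / d_old),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        bayes[:, g] = (sub[:, g] - g_old[:, None]) / np.sqrt(d_old[:, None])

    adjusted[ok] = bayes * np.sqrt(var_pooled[ok, None]) + grand_mean[ok, None]
    return matrix.with_values(adjusted)
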