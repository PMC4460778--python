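"""Gene-by-sample expression matrix with per-sample batch and class labels.

The :class:`ExpressionMatrix` is the single in-memory currency of every
analysis stage: integration consumes one per source dataset and emits a
merged one, biclustering and all downstream statistics read from it.
Values are held in a pandas DataFrame (rows = gene ids, columns = sample
ids); sample metadata is a parallel DataFrame indexed by sample id with
``batch`` and ``class`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Disease class vocabulary: five neurodegenerative diseases, three
#: psychiatric disorders, plus the control label.
DISEASES: tuple[str, ...] = ("AD", "ALS", "HD", "MS", "PD", "SCH", "BD", "AUT")
CONTROL = "CTRL"
CLASS_LABELS: tuple[str, ...] = DISEASES + (CONTROL,)


class MatrixError(ValueError):
    """Raised when an expression matrix violates its structural contract."""


@dataclass
class ExpressionMatrix:
    """Expression values plus sample metadata.

    Parameters
    ----------
    values
        genes x samples DataFrame; index = gene ids, columns = sample ids.
    sample_meta
        DataFrame indexed by sample id with columns ``batch`` and ``class``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    _validated: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        v, m = self.values, self.sample_meta
        if v.index.has_duplicates:
            raise MatrixError("duplicate gene ids")
        if v.columns.has_duplicates:
            raise MatrixError("duplicate sample ids")
        missing_cols = {"batch", "class"} - set(m.columns)
        if missing_cols:
            raise MatrixError(f"sample_meta lacks columns: {sorted(missing_cols)}")
        unknown = set(v.columns) - set(m.index)
        if unknown:
            raise MatrixError(f"samples without metadata: {sorted(unknown)[:5]}")
        bad = set(m.loc[list(v.columns), "class"]) - set(CLASS_LABELS)
        if bad:
            raise MatrixError(f"unknown class labels: {sorted(bad)}")
        self.sample_meta = m.loc[list(v.columns)]
        self._validated = True

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def batches(self) -> list[str]:
        return list(dict.fromkeys(self.sample_meta["batch"]))

    def samples_of_class(self, label: str) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["class"] == label])

    def samples_of_batch(self, batch: str) -> list[str]:
        meta = self.sample_meta
        return list(meta.index[meta["batch"] == batch])

    def class_map(self) -> dict[str, set[str]]:
        """Mapping class label -> sample-id set (only non-empty classes)."""
        out: dict[str, set[str]] = {}
        for label in CLASS_LABELS:
            ids = set(self.samples_of_class(label))
            if ids:
                out[label] = ids
        return out

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        v = self.values
        if genes is not None:
            v = v.loc[list(genes)]
        if samples is not None:
            v = v[list(samples)]
        return ExpressionMatrix(v.copy(), self.sample_meta.loc[list(v.columns)].copy())

    def with_values(self, arr: np.ndarray) -> "ExpressionMatrix":
        """Same genes/samples/metadata, new value array."""
        v = pd.DataFrame(arr, index=self.values.index, columns=self.values.columns)
        return ExpressionMatrix(v, self.sample_meta.copy())

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, expr_path, meta_path=None) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene_id")
        if meta_path is not None:
            meta = self.sample_meta.reset_index()
            meta.columns = ["sample_id", "batch", "class"]
            meta.to_csv(meta_path, sep="\t", index=False)


def read_expression_tsv(expr_path, meta_path) -> ExpressionMatrix:
    """Load an expression TSV (genes x samples) and its metadata TSV."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    return ExpressionMatrix(values, meta)


def read_metadata_tsv(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    return meta
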