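"""Synthetic multi-batch expression data with planted coexpression modules.

Real multi-cohort brain expression compendia cannot be shipped with the
package, so every downstream stage is exercised on generated data whose
ground truth is known exactly.  The generator emulates the structure the
analysis cares about:

* several batches (cohorts) with a fixed disease-class layout per batch,
* gene-wise additive and multiplicative batch effects,
* planted gene modules that are coexpressed only on the samples of chosen
  disease classes, with an analytically known average pairwise Pearson
  correlation.

Module genes follow a single-factor model on their member-class samples:

    x_gs = f_s + eps_gs,   f_s ~ N(0, 1),   eps_gs ~ N(0, sigma^2)

so the expected Pearson correlation between two module genes is
``1 / (1 + sigma^2)``; ``sigma`` is chosen from the requested
``within_pcc`` as ``sigma = sqrt(1/within_pcc - 1)``.  Outside the member
samples module genes are independent noise (or a second, weaker factor
when ``outside_pcc > 0``).  Background genes are independent noise with
standard deviation ``noise_sd`` everywhere; modelled as stably expressed
genes whose biological variance is a fraction of the disease-modulated
signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import CLASS_LABELS, CONTROL, ExpressionMatrix


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class BatchSpec:
    """One batch (cohort): its id and the per-class sample counts."""

    batch_id: str
    class_counts: dict[str, int]

    def validate(self) -> None:
        bad = set(self.class_counts) - set(CLASS_LABELS)
        if bad:
            raise ConfigurationError(f"batch {self.batch_id}: unknown classes {sorted(bad)}")
        if any(c < 0 for c in self.class_counts.values()):
            raise ConfigurationError(f"batch {self.batch_id}: negative sample count")
        if not any(c >= 3 for c in self.class_counts.values()):
            raise ConfigurationError(f"batch {self.batch_id}: no class with >=3 samples")

    @property
    def n_samples(self) -> int:
        return sum(self.class_counts.values())


@dataclass(frozen=True)
class PlantedModule:
    """A gene module coexpressed only on the samples of ``member_classes``.

    Outside its member classes a module gene keeps its own dynamic range
    (``outside_sd``, default 1.0 — the factor's scale): what distinguishes
    member samples is the *coordination* of the genes, not their
    amplitude.  With ``outside_pcc > 0`` the non-member samples get a
    second, weaker shared factor instead of independent noise.
    """

    module_id: str
    n_genes: int
    member_classes: frozenset[str]
    within_pcc: float
    outside_pcc: float = 0.0
    outside_sd: float = 1.0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ConfigurationError(f"module {self.module_id}: n_genes must be >= 2")
        if not self.member_classes:
            raise ConfigurationError(f"module {self.module_id}: empty member_classes")
        bad = set(self.member_classes) - set(CLASS_LABELS)
        if bad:
            raise ConfigurationError(f"module {self.module_id}: unknown classes {sorted(bad)}")
        if not (0.0 <= self.outside_pcc < self.within_pcc <= 1.0):
            raise ConfigurationError(
                f"module {self.module_id}: need 0 <= outside_pcc < within_pcc <= 1"
            )
        if self.outside_sd < 0:
            raise ConfigurationError(f"module {self.module_id}: outside_sd must be >= 0")

    @property
    def within_sigma(self) -> float:
        """Noise s.d. giving expected pairwise PCC = within_pcc."""
        return float(np.sqrt(1.0 / self.within_pcc - 1.0))


@dataclass(frozen=True)
class SyntheticConfig:
    n_background_genes: int
    batches: tuple[BatchSpec, ...]
    modules: tuple[PlantedModule, ...] = ()
    batch_additive_sd: float = 0.0
    batch_multiplicative_sd: float = 0.0
    noise_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if not self.batches:
            raise ConfigurationError("no batches configured")
        for b in self.batches:
            b.validate()
        ids = [b.batch_id for b in self.batches]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate batch ids")
        mids = [m.module_id for m in self.modules]
        if len(set(mids)) != len(mids):
            raise ConfigurationError("duplicate module ids")
        present = {c for b in self.batches for c, n in b.class_counts.items() if n > 0}
        for m in self.modules:
            m.validate()
            absent = set(m.member_classes) - present
            if absent:
                raise ConfigurationError(
                    f"module {m.module_id}: member classes {sorted(absent)} "
                    "absent from every batch"
                )
            n_member = sum(
                n for b in self.batches for c, n in b.class_counts.items()
                if c in m.member_classes
            )
            if n_member < 3:
                raise ConfigurationError(
                    f"module {m.module_id}: fewer than 3 member samples"
                )
        for name in ("batch_additive_sd", "batch_multiplicative_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_background_genes < 0:
            raise ConfigurationError("n_background_genes must be >= 0")

    @property
    def n_samples(self) -> int:
        return sum(b.n_samples for b in self.batches)

    @property
    def n_genes(self) -> int:
        return self.n_background_genes + sum(m.n_genes for m in self.modules)


@dataclass
class PlantedTruth:
    """Ground truth: per module, its gene ids and all member-class sample ids."""

    modules: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def genes_of(self, module_id: str) -> list[str]:
        return self.modules[module_id]["genes"]

    def samples_of(self, module_id: str) -> list[str]:
        return self.modules[module_id]["samples"]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.modules, indent=1, sort_keys=True))


def _sample_table(config: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for b in config.batches:
        for cls in CLASS_LABELS:
            for i in range(b.class_counts.get(cls, 0)):
                rows.append((f"{b.batch_id}_{cls}_{i:02d}", b.batch_id, cls))
    return pd.DataFrame(rows, columns=["sample_id", "batch", "class"]).set_index(
        "sample_id"
    )


def generate_dataset(config: SyntheticConfig) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Generate one multi-batch expression matrix plus its planted truth.

    All randomness flows from ``config.seed`` through a single
    ``numpy.random.Generator``; identical configs give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = _sample_table(config)
    sample_ids = list(meta.index)
    n_samples = len(sample_ids)

    gene_ids: list[str] = [f"BG{i:04d}" for i in range(config.n_background_genes)]
    truth = PlantedTruth()
    module_rows: list[tuple[PlantedModule, slice]] = []
    for m in config.modules:
        start = len(gene_ids)
        gene_ids.extend(f"{m.module_id}_g{j:02d}" for j in range(m.n_genes))
        module_rows.append((m, slice(start, start + m.n_genes)))

    # background: independent noise everywhere
    values = rng.normal(0.0, config.noise_sd, size=(len(gene_ids), n_samples))

    cls = meta["class"].to_numpy()
    for m, rows in module_rows:
        member = np.isin(cls, list(m.member_classes))
        k_in = int(member.sum())
        f_in = rng.normal(0.0, 1.0, size=k_in)
        eps = rng.normal(0.0, m.within_sigma, size=(m.n_genes, k_in))
        tmp = values[rows]
        tmp[:, member] = f_in[None, :] + eps
        k_out = n_samples - k_in
        if m.outside_pcc > 0.0:
            sig_out = float(np.sqrt(1.0 / m.outside_pcc - 1.0))
            f_out = rng.normal(0.0, 1.0, size=k_out)
            scale = m.outside_sd / np.sqrt(1.0 + sig_out**2)
            tmp[:, ~member] = scale * (
                f_out[None, :] + rng.normal(0.0, sig_out, size=(m.n_genes, k_out))
            )
        else:
            tmp[:, ~member] = rng.normal(0.0, m.outside_sd, size=(m.n_genes, k_out))
        values[rows] = tmp
        truth.modules[m.module_id] = {
            "genes": gene_ids[rows],
            "samples": [s for s, mem in zip(sample_ids, member) if mem],
        }

    # gene-wise batch effects: multiplicative scale then additive shift
    batch = meta["batch"].to_numpy()
    for b in config.batches:
        in_batch = batch == b.batch_id
        add = rng.normal(0.0, config.batch_additive_sd, size=len(gene_ids))
        mult = rng.lognormal(0.0, config.batch_multiplicative_sd, size=len(gene_ids))
        values[:, in_batch] = values[:, in_batch] * mult[:, None] + add[:, None]

    frame = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    return ExpressionMatrix(frame, meta), truth


# ---------------------------------------------------------------------------
# Study-layout fixture


def study_batches() -> tuple[BatchSpec, ...]:
    """The three-cohort class layout used throughout the tests.

    One cohort holds the six classes measured together (AD, ALS, HD, MS,
    PD, SCH plus controls), one holds bipolar disorder vs controls, one
    autism vs controls; 237 samples in total.
    """
    return (
        BatchSpec(
            "batch1",
            {"AD": 11, "ALS": 10, "HD": 10, "MS": 10, "PD": 12, "SCH": 10, CONTROL: 55},
        ),
        BatchSpec("batch2", {"BD": 30, CONTROL: 31}),
        BatchSpec("batch3", {"AUT": 29, CONTROL: 29}),
    )


def study_config(
    modules: tuple[PlantedModule, ...] = (),
    n_background_genes: int = 500,
    seed: int = 0,
    batch_additive_sd: float = 0.5,
    batch_multiplicative_sd: float = 0.2,
    noise_sd: float = 0.25,
) -> SyntheticConfig:
    """Desk-scale config mirroring the three-cohort study layout."""
    return SyntheticConfig(
        n_background_genes=n_background_genes,
        batches=study_batches(),
        modules=modules,
        batch_additive_sd=batch_additive_sd,
        batch_multiplicative_sd=batch_multiplicative_sd,
        noise_sd=noise_sd,
        seed=seed,
    )


def write_dataset(matrix: ExpressionMatrix, truth: PlantedTruth, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "truth": str(out / "truth.json"),
    }
    matrix.to_tsv(paths["expression"], paths["metadata"])
    truth.to_json(paths["truth"])
    return paths


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a plain dict (YAML-friendly)."""
    batches = tuple(
        BatchSpec(b["batch_id"], {k: int(v) for k, v in b["class_counts"].items()})
        for b in d.get("batches", [])
    )
    modules = tuple(
        PlantedModule(
            m["module_id"],
            int(m["n_genes"]),
            frozenset(m["member_classes"]),
            float(m["within_pcc"]),
            float(m.get("outside_pcc", 0.0)),
            float(m.get("outside_sd", 1.0)),
        )
        for m in d.get("modules", [])
    )
    return SyntheticConfig(
        n_background_genes=int(d.get("n_background_genes", 500)),
        batches=batches,
        modules=modules,
        batch_additive_sd=float(d.get("batch_additive_sd", 0.0)),
        batch_multiplicative_sd=float(d.get("batch_multiplicative_sd", 0.0)),
        noise_sd=float(d.get("noise_sd", 0.25)),
        seed=int(d.get("seed", 0)),
    )
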