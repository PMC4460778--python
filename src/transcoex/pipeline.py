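"""End-to-end orchestration: synth -> integrate -> biclic -> refine -> share -> enrich.

One YAML config and one master seed drive the whole run; per-stage seeds
are derived deterministically from the master seed and the stage name,
so any stage can be reproduced in isolation.  Each stage writes its
outputs under the run directory, first to a ``.partial`` file that is
renamed on success, and the run ends with a JSON manifest recording
every parameter, output path, count and elapsed time needed to
reproduce the result.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
import zlib
from pathlib import Path

import pandas as pd
import yaml

from . import biclic as _biclic
from . import enrichment as _enrich
from . import integration as _integration
from . import refinement as _refine
from . import sharing as _share
from . import synthetic as _synth
from .matrix import ExpressionMatrix, read_expression_tsv

log = logging.getLogger("transcoex")


class ConfigurationError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(master_seed: int, stage: str) -> int:
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int
    synth: dict | None = None
    expression: list[str] | None = None
    metadata: str | None = None
    probe_map: str | None = None
    unlog: dict | None = None  # dataset/batch id -> log base
    #: apply per-dataset quantile normalization before stacking; true is the
    #: right setting for real intensity data from heterogeneous platforms,
    #: synthetic runs set it to false (see docs/methods.md).
    quantile: bool = True
    biclic: dict = dataclasses.field(default_factory=dict)
    refine: dict = dataclasses.field(default_factory=dict)
    share: dict = dataclasses.field(default_factory=dict)
    enrich: dict | None = None
    stages: dict = dataclasses.field(default_factory=dict)  # name -> bool

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "seed" not in raw:
            raise ConfigurationError("config must set a seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def validate(self) -> None:
        if self.synth is None:
            if self.enabled("integrate"):
                if not self.expression or not self.metadata:
                    raise ConfigurationError(
                        "without a synth stage, expression and metadata paths are required"
                    )
                for p in list(self.expression) + [self.metadata]:
                    if not Path(p).exists():
                        raise ConfigurationError(f"input path does not exist: {p}")
        if self.probe_map and not Path(self.probe_map).exists():
            raise ConfigurationError(f"probe map does not exist: {self.probe_map}")


def _finalize(partial: Path) -> Path:
    final = Path(str(partial)[: -len(".partial")])
    os.replace(partial, final)
    return final


def _write_stage(path: Path, writer) -> Path:
    partial = Path(str(path) + ".partial")
    writer(partial)
    return _finalize(partial)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "parameters": {}}

    def record(stage: str, t0: float, **info) -> None:
        info["elapsed_s"] = round(time.time() - t0, 3)
        manifest["stages"][stage] = info
        log.info("stage %s done in %.2fs: %s", stage, info["elapsed_s"], info)

    matrix: ExpressionMatrix | None = None
    truth = None

    # -- synth -------------------------------------------------------------
    if config.synth is not None and config.enabled("synth"):
        t0 = time.time()
        try:
            synth_cfg = _synth.config_from_dict(
                {**config.synth, "seed": stage_seed(config.seed, "synth")}
            )
            matrix, truth = _synth.generate_dataset(synth_cfg)
            paths = _synth.write_dataset(matrix, truth, out / "synth")
        except Exception as e:  # noqa: BLE001
            raise StageError("synth", e) from e
        record(
            "synth",
            t0,
            outputs=paths,
            n_genes=matrix.n_genes,
            n_samples=matrix.n_samples,
        )
        manifest["parameters"]["synth"] = config.synth

    # -- integrate ---------------------------------------------------------
    if config.enabled("integrate"):
        t0 = time.time()
        try:
            if matrix is not None:
                parts = [
                    matrix.subset(samples=matrix.samples_of_batch(b))
                    for b in matrix.batches()
                ]
            else:
                meta = pd.read_csv(
                    config.metadata, sep="\t", dtype=str
                ).set_index("sample_id")
                parts = []
                for p in config.expression:
                    values = pd.read_csv(p, sep="\t", index_col=0)
                    values.index = values.index.astype(str)
                    parts.append(
                        ExpressionMatrix(values, meta.loc[list(values.columns)])
                    )
            unlog = config.unlog or {}
            processed = []
            for part in parts:
                batch = part.batches()[0]
                if batch in unlog:
                    part = _integration.unlog_transform(part, float(unlog[batch]))
                if config.probe_map:
                    pm = _integration.read_probe_map(config.probe_map)
                    part = _integration.collapse_probes(part, pm)
                if config.quantile:
                    part = _integration.quantile_normalize(part)
                processed.append(part)
            merged = _integration.intersect_and_stack(processed)
            merged = _integration.combat_adjust(merged)
            expr_path = _write_stage(
                out / "merged.tsv", lambda p: merged.to_tsv(p)
            )
            meta_path = _write_stage(
                out / "merged_meta.tsv",
                lambda p: merged.sample_meta.reset_index()
                .set_axis(["sample_id", "batch", "class"], axis=1)
                .to_csv(p, sep="\t", index=False),
            )
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("integrate", e) from e
        matrix = merged
        record(
            "integrate",
            t0,
            outputs={"expression": str(expr_path), "metadata": str(meta_path)},
            n_genes=merged.n_genes,
            n_samples=merged.n_samples,
        )

    if matrix is None:
        raise ConfigurationError("no expression data: enable synth or integrate")

    # -- biclic ------------------------------------------------------------
    biclusters = []
    if config.enabled("biclic"):
        t0 = time.time()
        try:
            params = _biclic.BiclicParams(**config.biclic)
            biclusters = _biclic.run_biclic(matrix, params)
            bic_path = _write_stage(
                out / "biclusters.json",
                lambda p: p.write_text(
                    json.dumps([b.to_dict() for b in biclusters], indent=1)
                ),
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("biclic", e) from e
        record("biclic", t0, outputs={"biclusters": str(bic_path)}, n_biclusters=len(biclusters))
        manifest["parameters"]["biclic"] = dataclasses.asdict(params)

    # -- refine ------------------------------------------------------------
    refined = []
    if config.enabled("refine"):
        t0 = time.time()
        try:
            alpha = float(config.refine.get("alpha", 0.005))
            n_draws = int(config.refine.get("n_draws", 100_000))
            refined = _refine.refine_all(
                biclusters,
                matrix,
                alpha=alpha,
                n_draws=n_draws,
                seed=stage_seed(config.seed, "refine"),
            )
            ref_path = _write_stage(
                out / "refined.tsv",
                lambda p: _refine.refined_to_frame(refined).to_csv(
                    p, sep="\t", index=False
                ),
            )
        except Exception as e:  # noqa: BLE001
            raise StageError("refine", e) from e
        record("refine", t0, outputs={"refined": str(ref_path)}, n_refined=len(refined))
        manifest["parameters"]["refine"] = {"alpha": alpha, "n_draws": n_draws}

    # -- share -------------------------------------------------------------
    if config.enabled("share") and refined:
        t0 = time.time()
        try:
            shared, specific = _share.partition_shared(refined)
            counts = _share.pairwise_counts(refined)
            counts_path = _write_stage(
                out / "pairwise_counts.tsv",
                lambda p: counts.to_csv(p, sep="\t"),
            )
            outputs = {"pairwise_counts": str(counts_path)}
            for name, group in (("shared", "shared"), ("specific", "specific")):
                tg = _share.top_genes(refined, group, k=30)
                path = _write_stage(
                    out / f"top_genes_{name}.tsv",
                    lambda p, tg=tg: pd.DataFrame(
                        tg, columns=["gene", "count"]
                    ).to_csv(p, sep="\t", index=False),
                )
                outputs[f"top_genes_{name}"] = str(path)
            if config.share.get("disease_genes"):
                dg = _share.read_disease_gene_tsv(config.share["disease_genes"])
                net = (
                    _share.read_edge_list_tsv(config.share["ppi"])
                    if config.share.get("ppi")
                    else None
                )
                overlap = _share.disease_gene_overlap(refined, dg, net)
                path = _write_stage(
                    out / "disease_gene_overlap.tsv",
                    lambda p: overlap.to_csv(p, sep="\t", index=False),
                )
                outputs["disease_gene_overlap"] = str(path)
        except Exception as e:  # noqa: BLE001
            raise StageError("share", e) from e
        record(
            "share",
            t0,
            outputs=outputs,
            n_shared=len(shared),
            n_specific=len(specific),
        )

    # -- enrich ------------------------------------------------------------
    if config.enrich and config.enabled("enrich") and refined:
        t0 = time.time()
        try:
            annotation = _enrich.read_gmt(
                config.enrich["gmt"], background=set(matrix.gene_ids)
            )
            alpha = float(config.enrich.get("alpha", 0.005))
            shared, specific = _share.partition_shared(refined)
            profiles = {}
            if config.enrich.get("category_map"):
                cmap = _enrich.read_category_map(config.enrich["category_map"])
                for name, group in (("shared", shared), ("specific", specific)):
                    hits = [
                        _enrich.hypergeom_enrich(s.genes, annotation, alpha)
                        for s in group
                    ]
                    profiles[name] = _enrich.category_profile(hits, cmap)
                fold = _enrich.fold_comparison(profiles["shared"], profiles["specific"])
                path = _write_stage(
                    out / "category_fold.tsv",
                    lambda p: fold.to_csv(p, sep="\t", index=False),
                )
                outputs = {"category_fold": str(path)}
            else:
                rows = []
                for s in refined:
                    for tid, name, p_, q_ in _enrich.hypergeom_enrich(
                        s.genes, annotation, alpha
                    ):
                        rows.append(
                            (",".join(sorted(s.genes)), tid, name, p_, q_)
                        )
                df = pd.DataFrame(
                    rows, columns=["genes", "term_id", "term_name", "p", "q"]
                )
                path = _write_stage(
                    out / "enrichment.tsv",
                    lambda p: df.to_csv(p, sep="\t", index=False),
                )
                outputs = {"enrichment": str(path)}
        except Exception as e:  # noqa: BLE001
            raise StageError("enrich", e) from e
        record("enrich", t0, outputs=outputs)

    # -- truth bookkeeping for recovery checks ------------------------------
    if truth is not None:
        manifest["planted_modules"] = sorted(truth.modules)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    manifest["manifest_path"] = str(manifest_path)
    return manifest
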