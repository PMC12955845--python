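"""Pipeline configuration and end-to-end orchestration.

A single YAML file (or PipelineConfig object) drives the full chain
synth/ingest -> extract -> train -> cluster -> prevalence -> associate ->
survival. One top-level seed fans out deterministically to per-stage seeds
via NumPy SeedSequence spawning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import downstream, io_ingest, synthetic, views
from .model import ModelConfig, embed_all, save_model, train

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seeds"]


@dataclass
class PipelineConfig:
    out_dir: str = "hmivae_out"
    seed: int = 0
    # input: either explicit sample triplets or a synthetic spec
    samples: list = field(default_factory=list)  # [{stack, mask, channels, sample_id}]
    clinical_path: str | None = None
    use_synthetic: bool = True
    synthetic: dict = field(default_factory=dict)
    # feature extraction
    k_spatial_neighbours: int = views.DEFAULT_K_NEIGHBOURS
    # model
    model: dict = field(default_factory=dict)
    # clustering
    cluster_neighbours: int = downstream.DEFAULT_CLUSTER_NEIGHBOURS
    resolutions: dict = field(default_factory=lambda: dict(downstream.DEFAULT_RESOLUTIONS))
    # association
    alpha: float = 0.05
    min_category_size: int = 5
    clinical_variables: list = field(default_factory=lambda: ["group", "grade", "stage"])

    def validate(self) -> None:
        if self.k_spatial_neighbours < 1:
            raise ValueError("k_spatial_neighbours must be >= 1")
        if self.cluster_neighbours < 1:
            raise ValueError("cluster_neighbours must be >= 1")
        if not self.use_synthetic:
            if not self.samples:
                raise ValueError("no input samples configured and use_synthetic is false")
            for s in self.samples:
                for key in ("stack", "mask", "channels"):
                    if not Path(s[key]).exists():
                        raise ValueError(f"missing input path: {s[key]}")
            if self.clinical_path and not Path(self.clinical_path).exists():
                raise ValueError(f"missing clinical table: {self.clinical_path}")
        unknown = set(self.resolutions) - set(downstream.DEFAULT_RESOLUTIONS)
        if unknown:
            raise ValueError(f"unknown embedding spaces in resolutions: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def stage_seeds(seed: int) -> dict:
    """Deterministic per-stage seeds fanned out from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    names = ["synth", "train", "cluster", "project"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31 - 1)) for n, c in zip(names, children)}


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute all stages in order; returns the artifact directory."""
    cfg.validate()
    seeds = stage_seeds(cfg.seed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        if cfg.use_synthetic:
            stage = "synth"
            spec = synthetic.SyntheticSpec(**{"seed": seeds["synth"], **cfg.synthetic})
            ds = synthetic.generate(spec)
            samples = ds.samples
            clinical = ds.clinical
            io_ingest.write_table(ds.ground_truth, out / "ground_truth.csv")
            io_ingest.write_table(clinical, out / "clinical.csv")
        else:
            samples = [
                io_ingest.load_sample(
                    s["stack"], s["mask"], s["channels"], sample_id=s.get("sample_id")
                )
                for s in cfg.samples
            ]
            clinical = (
                io_ingest.load_clinical(cfg.clinical_path) if cfg.clinical_path else None
            )
        logger.info(
            "stage=%s seed=%s config=%s n_samples=%d",
            stage,
            cfg.seed,
            cfg.config_hash(),
            len(samples),
        )

        stage = "extract"
        cv = views.extract_views(samples, k=cfg.k_spatial_neighbours)
        io_ingest.save_cellviews(cv, out / "cellviews.h5ad")
        logger.info("stage=extract n_cells=%d n_proteins=%d", cv.n_cells, cv.n_proteins)

        stage = "train"
        mcfg = ModelConfig(**{"seed": seeds["train"], **cfg.model})
        mdl, log = train(cv, mcfg)
        save_model(mdl, out / "model.ckpt")
        io_ingest.write_table(pd.DataFrame(log), out / "training_log.csv")
        latents = embed_all(mdl, cv)

        stage = "cluster"
        labels = {}
        spaces = list(cfg.resolutions)
        for space in spaces:
            emb = latents.embedding(space)
            n_nb = min(cfg.cluster_neighbours, cv.n_cells - 1)
            labels[space] = downstream.cluster(
                emb,
                n_neighbours=n_nb,
                resolution=cfg.resolutions[space],
                seed=seeds["cluster"],
            )
        assign = pd.DataFrame(
            {
                "cell_id": cv.cell_ids,
                "sample_id": cv.sample_ids,
                **{f"cluster_{s}": labels[s] for s in spaces},
            }
        )
        io_ingest.write_table(assign, out / "clusters.csv")

        stage = "prevalence"
        prev = downstream.prevalence(labels["integrated"], cv.sample_ids, cv.sample_dims)
        io_ingest.write_table(prev, out / "prevalence.csv")

        if clinical is not None:
            variables = [v for v in cfg.clinical_variables if v in clinical.columns]
            stage = "associate"
            assoc = downstream.associate_proportion(
                prev, clinical, variables, min_samples=cfg.min_category_size
            )
            if len(assoc):
                io_ingest.write_table(assoc, out / "associations.csv")
            lat_assoc = downstream.associate_latent(
                latents.z,
                cv.sample_ids,
                clinical,
                variables,
                min_samples=cfg.min_category_size,
            )
            if len(lat_assoc):
                io_ingest.write_table(lat_assoc, out / "latent_associations.csv")
            enough_for_cox = (
                "survival_time" in clinical.columns
                and clinical["event_indicator"].sum() >= 3
                and len(clinical) >= 10
            )
            if enough_for_cox:
                stage = "survival"
                surv = downstream.survival(prev, clinical)
                io_ingest.write_table(surv, out / "survival.csv")
            elif "survival_time" in clinical.columns:
                logger.warning("too few samples/events for Cox models; survival skipped")
    except Exception as exc:  # noqa: BLE001 - halt with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
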