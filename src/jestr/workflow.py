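"""End-to-end pipeline: simulate -> train -> rank -> evaluate, plus ablations.

A single layered YAML config drives everything; a run directory receives
the config snapshot, per-epoch metrics, checkpoint, evaluation report and
a manifest recording seeds, config hash and artifact paths, so any stage
can be replayed in isolation from the standard-format files it wrote.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .encoders import EncoderParams, save_weights
from .objective import ObjectiveConfig
from .ranking import evaluate, similarity_distributions
from .synthetic import GeneratorConfig, generate_dataset
from .training import TrainingConfig, train, _GraphCache

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys."""


@dataclass
class PipelineConfig:
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    evaluation_ks: tuple[int, ...] = (1, 5, 20)


@dataclass
class RunManifest:
    config: dict
    seeds: dict
    config_hash: str
    artifacts: dict
    timings_s: dict
    status: str = "ok"

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _build_dataclass(cls, data: dict, path: str):
    """Strict dataclass construction: unknown keys are config errors."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown config key {path}.{key}")
        sub = fields[key].type
        if isinstance(value, dict) and key in _NESTED:
            kwargs[key] = _build_dataclass(_NESTED[key], value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


_NESTED = {
    "generator": GeneratorConfig,
    "training": TrainingConfig,
    "encoder": EncoderParams,
    "objective": ObjectiveConfig,
}


def load_config(path: str | Path | dict) -> PipelineConfig:
    data = path if isinstance(path, dict) else (
        yaml.safe_load(Path(path).read_text()) or {}
    )
    cfg = _build_dataclass(PipelineConfig, data, "config")
    # one master seed flows into every stage unless explicitly overridden
    if "seed" in data:
        if not (isinstance(data.get("generator"), dict) and "seed" in data["generator"]):
            cfg.generator.seed = cfg.seed
        tdata = data.get("training") or {}
        if "seed" not in tdata:
            cfg.training.seed = cfg.seed
        if not (isinstance(tdata.get("encoder"), dict) and "seed" in tdata["encoder"]):
            cfg.training.encoder.seed = cfg.seed
    return cfg


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> RunManifest:
    """Execute simulate -> train -> rank -> evaluate under one seeded config."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(cfg)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    (out / "config.yaml").write_text(yaml.safe_dump(cfg_dict))

    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    )
    root = logging.getLogger("jestr")
    root.addHandler(handler)
    log.info("run start: seed=%d config_hash=%s", cfg.seed, cfg_hash)

    timings: dict[str, float] = {}
    t0 = time.time()
    data = generate_dataset(cfg.generator)
    data.write(out / "data")
    timings["simulate"] = time.time() - t0
    log.info("simulated %d molecules / %d spectra", len(data.molecules),
             len(data.dataset.spectra))

    t0 = time.time()
    weights, report = train(data.train, cfg.training)
    save_weights(weights, cfg.training.encoder, out / "checkpoint.npz")
    report.to_frame().to_csv(out / "metrics.tsv", sep="\t", index=False)
    timings["train"] = time.time() - t0

    t0 = time.time()
    ev = evaluate(data.test, weights, cfg.training.encoder, ks=cfg.evaluation_ks)
    ev.to_json(out / "evaluation.json")
    ev.to_tsv(out / "rank_curve.tsv")
    dist = similarity_distributions(data.test, weights, cfg.training.encoder)
    (out / "similarity.json").write_text(json.dumps(dist, indent=2))
    timings["evaluate"] = time.time() - t0

    manifest = RunManifest(
        config=cfg_dict,
        seeds={"master": cfg.seed, "generator": cfg.generator.seed,
               "training": cfg.training.seed},
        config_hash=cfg_hash,
        artifacts={
            "data": str(out / "data"),
            "checkpoint": str(out / "checkpoint.npz"),
            "metrics": str(out / "metrics.tsv"),
            "evaluation": str(out / "evaluation.json"),
        },
        timings_s=timings,
    )
    manifest.write(out / "manifest.json")
    log.info("run complete: %s", out)
    root.removeHandler(handler)
    handler.close()
    return manifest


def ablation_suite(
    config: str | Path | dict,
    variants: tuple[str, ...] = ("losses", "regularization"),
) -> "pd.DataFrame":
    """Train the loss/scoring variants and the regularization on/off pair
    on one shared synthetic dataset; returns a rank@k comparison table.

    The regularization pair shares its first-phase training: both branches
    resume from the epoch-boundary state and differ only in the final
    fine-tuning epochs, which isolates the effect of the candidate term.
    """
    import copy

    import pandas as pd

    cfg = load_config(config)
    data = generate_dataset(cfg.generator)
    rows = []
    cache = _GraphCache()

    def eval_row(name, weights, tcfg, score):
        ev = evaluate(data.test, weights, tcfg.encoder, score=score,
                      ks=cfg.evaluation_ks)
        dist = similarity_distributions(data.test, weights, tcfg.encoder)
        rows.append({"variant": name,
                     **{f"rank@{k}": ev.rank_at_k[k] for k in cfg.evaluation_ks},
                     "candidate_cosine_mean": dist["candidate_mean"]})

    if "losses" in variants:
        for name, loss_variant, score in (
            ("infonce+cosine", "infonce_cosine", "cosine"),
            ("ce_dotproduct+dotproduct", "ce_dotproduct", "dotproduct"),
            ("ce_dotproduct+cosine", "ce_dotproduct", "cosine"),
        ):
            tcfg = copy.deepcopy(cfg.training)
            tcfg.objective.loss_variant = loss_variant  # type: ignore[assignment]
            w, _ = train(data.train, tcfg, graph_cache=cache)
            eval_row(name, w, tcfg, score)

    if "regularization" in variants:
        tcfg = copy.deepcopy(cfg.training)
        boundary = min(
            int(tcfg.objective.reg_start_fraction * tcfg.epochs), tcfg.epochs - 1
        )
        base_cfg = copy.deepcopy(tcfg)
        base_cfg.epochs = boundary
        shared_w, _, opt = train(data.train, base_cfg, graph_cache=cache,
                                 return_optimizer=True)
        for name, reg in (("regularized", True), ("no_regularization", False)):
            branch = copy.deepcopy(tcfg)
            if not reg:
                branch.objective.reg_weight = 0.0
            w = {k: type(t)(t.data.copy(), requires_grad=True)
                 for k, t in shared_w.items()}
            w, _ = train(data.train, branch, weights=w,
                         start_epoch=boundary + 1, graph_cache=cache,
                         optimizer=opt)
            eval_row(name, w, branch, "cosine")

    return pd.DataFrame(rows)
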