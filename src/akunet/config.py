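"""Run configuration (YAML) and the end-to-end pipeline.

A :class:`RunConfig` nests one section per pipeline stage — scene
synthesis, crop extraction, model architecture, training, tiled
inference — plus a global seed.  Loading merges user YAML over defaults
and rejects unknown keys by their full path; every run writes the fully
resolved configuration back to disk so artifacts are reproducible from
(code, config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .metrics import aggregate, evaluate_pair
from .model import AKUNet, ModelConfig, build_model
from .patches import build_crop_arrays, split_by_patient
from .synthetic import SceneConfig, generate_dataset
from .tiling import detect_regions, plan_tiling, predict_wide
from .train import TrainConfig, fit
from .io import to_float

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "DataConfig", "PatchConfig", "TilingConfig",
           "load_config", "save_config", "run_end_to_end"]


@dataclass
class DataConfig:
    n_patients: int = 10
    images_per_patient: int = 2

    def to_dict(self):
        return dict(vars(self))


@dataclass
class PatchConfig:
    side: int = 512
    final_side: int = 256
    n_offsets: int = 8
    prescale: bool = True          # the first 0.5x rescale stage
    fractions: tuple = (0.8, 0.1, 0.1)

    def __post_init__(self):
        self.fractions = tuple(self.fractions)

    def to_dict(self):
        d = dict(vars(self))
        d["fractions"] = list(self.fractions)
        return d


@dataclass
class TilingConfig:
    overlap: int = 0
    threshold: float = 0.5
    min_area_px: int = 0

    def to_dict(self):
        return dict(vars(self))


@dataclass
class RunConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    data: DataConfig = field(default_factory=DataConfig)
    patches: PatchConfig = field(default_factory=PatchConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    seed: int = 0

    def to_dict(self):
        return {name: getattr(self, name).to_dict()
                if dataclasses.is_dataclass(getattr(self, name))
                else getattr(self, name)
                for name in ("scene", "data", "patches", "model", "train",
                             "tiling", "seed")}


_SECTIONS = {"scene": SceneConfig, "data": DataConfig, "patches": PatchConfig,
             "model": ModelConfig, "train": TrainConfig, "tiling": TilingConfig}


def _build_section(cls, values, path):
    valid = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, val in values.items():
        if key not in valid:
            raise KeyError(f"unknown configuration key {path}.{key}")
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration in section {path}: {exc}")


def from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, {}) or {}
        if not isinstance(section, dict):
            raise ValueError(f"section {name} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    if "seed" in data:
        kwargs["seed"] = int(data.pop("seed"))
    if data:
        raise KeyError(f"unknown configuration key(s): {sorted(data)}")
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Read YAML, merge over defaults, validate; unknown keys are
    rejected with their key path."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = from_dict(data or {})
    logger.info("resolved configuration: %s", cfg.to_dict())
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def run_end_to_end(cfg: RunConfig, out_dir) -> dict:
    """synth -> split -> crops -> train -> tiled predict -> score.

    Trains on crops from the train/validation patients, then runs tiled
    wide-field inference on the held-out test patients' full scenes and
    scores against their ground-truth masks.  Returns (and writes) a
    JSON report with aggregate Dice/IoU/aF1.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out_dir / "config.yaml")

    stage = "synthesis"
    try:
        images, index = generate_dataset(cfg.data.n_patients,
                                         cfg.data.images_per_patient,
                                         cfg.scene)

        stage = "splitting"
        manifest = split_by_patient(images, cfg.patches.fractions,
                                    seed=cfg.seed)
        manifest.validate()
        manifest.to_json(out_dir / "split.json")
        by_split = {
            name: [im for im in images if manifest.assignment[im.patient_id] == name]
            for name in ("train", "val", "test")}

        stage = "crop extraction"
        p = cfg.patches
        x_tr, y_tr, pid_tr = build_crop_arrays(
            by_split["train"], p.side, p.final_side, p.n_offsets,
            seed=cfg.seed, augment=True, prescale=p.prescale)
        x_va, y_va, pid_va = build_crop_arrays(
            by_split["val"], p.side, p.final_side, p.n_offsets,
            seed=cfg.seed + 1, augment=True, prescale=p.prescale)

        stage = "training"
        model = build_model(cfg.model, np.random.default_rng(cfg.seed))
        result = fit(model, (x_tr, y_tr), (x_va, y_va), cfg.train,
                     out_dir=out_dir, train_patients=pid_tr,
                     val_patients=pid_va)

        stage = "wide-field inference"
        reports = []
        for im in by_split["test"]:
            image = to_float(im.image)
            plan = plan_tiling(*image.shape[:2], cfg.model.input_side,
                               cfg.tiling.overlap)
            prob = predict_wide(image, model, plan)
            mask, _ = detect_regions(prob, cfg.tiling.threshold,
                                     cfg.tiling.min_area_px)
            reports.append(evaluate_pair(mask.astype(np.float32), im.mask))

        stage = "reporting"
        test_patients = manifest.patients("test")
        train_patients = manifest.patients("train")
        assert not set(test_patients) & set(train_patients)
        report = {
            "patients": manifest.counts.get("patients", {}),
            "train_patients": train_patients,
            "val_patients": manifest.patients("val"),
            "test_patients": test_patients,
            "n_train_crops": int(len(x_tr)),
            "n_val_crops": int(len(x_va)),
            "best_epoch": result.best_epoch,
            "best_val_dice": result.best_val_dice,
            "wide_field": aggregate(reports),
        }
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed during {stage}: {exc}") from exc
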