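"""End-to-end experiment workflow: configuration, seeding, artifacts.

An experiment is described by one YAML file and a single global seed;
every stage (generation, augmentation, splitting, initialization,
training) derives its own seed from the global one by stable hashing,
so a rerun of the same configuration is bit-for-bit reproducible and a
stage can be re-executed in isolation.

The workflow recasts the clinical validation loop (acquire -> screen ->
preprocess -> segment) as: generate/ingest -> augment -> split -> train
-> evaluate -> predict/overlay.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
import yaml

from .augment import augment_dataset
from .data_io import Sample, read_image, split_dataset, write_image, write_mask, read_mask
from .estimator import desk_model_config, desk_train_config
from .eval import evaluate, overlay
from .net import ModelConfig, build_improved_unet, predict
from .synthetic import SyntheticParams, generate_dataset
from .train import TrainConfig, preprocess_batch, train_model

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "stage_seed",
    "save_checkpoint",
    "load_checkpoint",
    "write_manifest",
    "load_manifest",
    "run_experiment",
    "validate_external_image",
]


class ConfigError(ValueError):
    """Raised for unknown or invalid configuration keys, before any compute."""


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed fan-out from one global seed."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


_TOP_KEYS = {"seed", "output_dir", "data", "augment", "split", "model", "train", "eval"}
_DATA_KEYS = {"synthetic", "manifest", "n"}
_AUG_KEYS = {"ops", "crops_per_sample", "crop_size"}
_SPLIT_KEYS = {"train_fraction"}
_EVAL_KEYS = {"overlay_count"}


def _check_keys(section: dict, allowed, where: str):
    for key in section:
        if key not in allowed:
            raise ConfigError(f"unknown configuration key '{where}.{key}'")


def _build_dataclass(cls, section: dict, where: str, **extra):
    names = {f.name for f in dataclasses.fields(cls)}
    _check_keys(section, names, where)
    kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in section.items()}
    kwargs.update(extra)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid '{where}' configuration: {exc}") from exc


@dataclasses.dataclass
class ExperimentConfig:
    """Validated, fully-resolved experiment description."""

    seed: int
    output_dir: Path
    synthetic_params: Optional[SyntheticParams]
    n_samples: int
    manifest_path: Optional[Path]
    augment_ops: tuple
    crops_per_sample: int
    crop_size: Optional[tuple]
    train_fraction: float
    model: ModelConfig
    train: TrainConfig
    overlay_count: int
    raw: dict

    @classmethod
    def from_dict(cls, doc: dict, base_dir: Path = Path(".")) -> "ExperimentConfig":
        if not isinstance(doc, dict):
            raise ConfigError("configuration root must be a mapping")
        _check_keys(doc, _TOP_KEYS, "<root>")
        seed = int(doc.get("seed", 0))
        output_dir = Path(doc.get("output_dir", "fissureseg_run"))
        if not output_dir.is_absolute():
            output_dir = base_dir / output_dir

        data = doc.get("data", {"synthetic": {}})
        _check_keys(data, _DATA_KEYS, "data")
        synthetic_params = None
        manifest_path = None
        n_samples = int(data.get("n", 32))
        if "manifest" in data:
            manifest_path = Path(data["manifest"])
            if not manifest_path.is_absolute():
                manifest_path = base_dir / manifest_path
        else:
            syn = dict(data.get("synthetic") or {})
            syn.pop("seed", None)  # the global seed governs generation
            synthetic_params = _build_dataclass(
                SyntheticParams, syn, "data.synthetic", seed=stage_seed(seed, "generate")
            )

        aug = doc.get("augment", {})
        _check_keys(aug, _AUG_KEYS, "augment")
        augment_ops = tuple(aug.get("ops", ("orbit",)))
        crops_per_sample = int(aug.get("crops_per_sample", 0))
        crop_size = tuple(aug["crop_size"]) if "crop_size" in aug else None

        split = doc.get("split", {})
        _check_keys(split, _SPLIT_KEYS, "split")
        train_fraction = float(split.get("train_fraction", 0.7))

        model_section = dict(doc.get("model", {}))
        model = _build_dataclass(ModelConfig, {**_desk_model_defaults(), **model_section}, "model")

        train_section = dict(doc.get("train", {}))
        train_section.pop("seed", None)
        train = _build_dataclass(
            TrainConfig,
            {**_desk_train_defaults(), **train_section},
            "train",
            seed=stage_seed(seed, "train"),
        )
        if tuple(train.input_size) != tuple(model.input_size):
            train = dataclasses.replace(train, input_size=tuple(model.input_size))

        ev = doc.get("eval", {})
        _check_keys(ev, _EVAL_KEYS, "eval")
        overlay_count = int(ev.get("overlay_count", 2))
        return cls(
            seed=seed,
            output_dir=output_dir,
            synthetic_params=synthetic_params,
            n_samples=n_samples,
            manifest_path=manifest_path,
            augment_ops=augment_ops,
            crops_per_sample=crops_per_sample,
            crop_size=crop_size,
            train_fraction=train_fraction,
            model=model,
            train=train,
            overlay_count=overlay_count,
            raw=doc,
        )

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        return cls.from_dict(doc, base_dir=path.parent)


def _desk_model_defaults():
    return dataclasses.asdict(desk_model_config())


def _desk_train_defaults():
    d = dataclasses.asdict(desk_train_config())
    d.pop("seed")
    return d


# ---------------------------------------------------------------------------
# Checkpoints and manifests


def save_checkpoint(model, model_config: ModelConfig, path) -> None:
    """Self-describing checkpoint: weights plus the config that rebuilds them."""
    state = model.state_dict()
    meta = json.dumps(dataclasses.asdict(model_config))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path):
    """Rebuild the model recorded in a checkpoint; returns (model, config)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        state = {k: data[k] for k in data.files if k != "__config__"}
    for key in ("input_size",):
        if key in meta and isinstance(meta[key], list):
            meta[key] = tuple(meta[key])
    config = ModelConfig(**meta)
    model = build_improved_unet(config, seed=0)
    model.load_state_dict(state)
    return model, config


def write_manifest(samples: List[Sample], out_dir, params_record=None) -> Path:
    """Write image/mask PNG pairs plus a JSON manifest listing them."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in samples:
        img_name = f"{s.identifier}.png"
        write_image(s.image, out_dir / img_name)
        entry = {"id": s.identifier, "image": img_name}
        if s.mask is not None:
            mask_name = f"{s.identifier}_mask.png"
            write_mask(s.mask, out_dir / mask_name)
            entry["mask"] = mask_name
        entries.append(entry)
    manifest = {"samples": entries}
    if params_record is not None:
        manifest["params"] = params_record
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_manifest(path) -> List[Sample]:
    path = Path(path)
    doc = json.loads(path.read_text())
    samples = []
    for entry in doc["samples"]:
        image = read_image(path.parent / entry["image"])
        mask = read_mask(path.parent / entry["mask"]) if "mask" in entry else None
        samples.append(Sample(image, mask, identifier=entry["id"]))
    return samples


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_dumps_deterministic(obj) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, allow_nan=True)


# ---------------------------------------------------------------------------
# The workflow


def run_experiment(config) -> dict:
    """Execute generate/ingest -> augment -> split -> train -> evaluate.

    `config` may be a path to a YAML file, a dict, or an ExperimentConfig.
    Writes checkpoint, history CSV, metrics JSON, overlay PNGs for held-out
    samples, and a provenance manifest; returns the artifact paths.
    """
    if isinstance(config, (str, Path)):
        config = ExperimentConfig.from_file(config)
    elif isinstance(config, dict):
        config = ExperimentConfig.from_dict(config)
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)

    if config.manifest_path is not None:
        pool = load_manifest(config.manifest_path)
    else:
        pool = generate_dataset(
            config.synthetic_params, config.n_samples, stage_seed(config.seed, "generate")
        )

    ids = list(range(len(pool)))
    outer = split_dataset(ids, config.train_fraction, stage_seed(config.seed, "outer-split"))
    trainval_pool = [pool[i] for i in outer.train_ids]
    held_out = [pool[i] for i in outer.held_out_ids]

    amplified = augment_dataset(
        trainval_pool,
        ops=config.augment_ops,
        seed=stage_seed(config.seed, "augment"),
        crops_per_sample=config.crops_per_sample,
        crop_size=config.crop_size,
    )
    inner = split_dataset(
        list(range(len(amplified))), config.train_fraction, stage_seed(config.seed, "inner-split")
    )
    train_set = [amplified[i] for i in inner.train_ids]
    val_set = [amplified[i] for i in inner.held_out_ids]

    model = build_improved_unet(config.model, seed=stage_seed(config.seed, "init"))
    model, history = train_model(model, train_set, val_set, config.train)

    report = evaluate(model, held_out, config.train, num_classes=config.model.num_classes)

    checkpoint_path = out / "checkpoint.npz"
    save_checkpoint(model, config.model, checkpoint_path)
    history_path = out / "history.csv"
    pd.DataFrame([dataclasses.asdict(h) for h in history]).to_csv(history_path, index=False)
    metrics_path = out / "metrics.json"
    metrics = {
        "held_out": report.to_dict(),
        "n_train": len(train_set),
        "n_val": len(val_set),
        "n_held_out": len(held_out),
        "seed": config.seed,
    }
    metrics_path.write_text(_json_dumps_deterministic(metrics))

    overlay_paths = []
    k = min(config.overlay_count, len(held_out))
    if k > 0:
        images, _ = preprocess_batch(held_out[:k], config.train.input_size)
        preds = predict(model, images)
        for i in range(k):
            op = out / f"overlay_{held_out[i].identifier}.png"
            h, w = config.train.input_size
            from skimage.transform import resize as _resize

            base_img = held_out[i].image
            if base_img.shape[:2] != (h, w):
                base_img = np.clip(
                    _resize(base_img, (h, w), order=1, preserve_range=True), 0, 255
                ).astype(np.uint8)
            write_image(overlay(base_img, preds[i], color=(255, 0, 0), alpha=0.5), op)
            overlay_paths.append(op)

    artifact_paths = [checkpoint_path, history_path, metrics_path, *overlay_paths]
    manifest = {
        "seed": config.seed,
        "stage_seeds": {
            name: stage_seed(config.seed, name)
            for name in ("generate", "outer-split", "augment", "inner-split", "init", "train")
        },
        "artifacts": {p.name: _sha256(p) for p in artifact_paths},
    }
    (out / "run_manifest.json").write_text(_json_dumps_deterministic(manifest))
    return {
        "checkpoint": checkpoint_path,
        "history": history_path,
        "metrics": metrics_path,
        "overlays": overlay_paths,
        "manifest": out / "run_manifest.json",
        "report": report,
    }


def validate_external_image(checkpoint_path, image_path, out_dir) -> dict:
    """Segment an image that took no part in training; never needs a mask.

    Reads the image (grayscale inputs are promoted to RGB), resizes it to
    the checkpoint's input size, predicts, and writes mask and overlay PNGs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, config = load_checkpoint(checkpoint_path)
    image = read_image(image_path)
    sample = Sample(image, None, identifier=Path(image_path).stem)
    images, _ = preprocess_batch([sample], tuple(config.input_size))
    pred = predict(model, images)[0]
    h, w = config.input_size
    from skimage.transform import resize as _resize

    shown = image
    if shown.shape[:2] != (h, w):
        shown = np.clip(_resize(shown, (h, w), order=1, preserve_range=True), 0, 255).astype(
            np.uint8
        )
    mask_path = out_dir / f"{sample.identifier}_mask.png"
    overlay_path = out_dir / f"{sample.identifier}_overlay.png"
    write_mask(pred, mask_path)
    write_image(overlay(shown, pred, color=(255, 0, 0), alpha=0.5), overlay_path)
    return {"mask": mask_path, "overlay": overlay_path, "prediction": pred}
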