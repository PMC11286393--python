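"""Readers and writers for images, transforms, manifests and run configs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .polywarp import PARAM_NAMES, PolynomialTransform, QuadraticTransform
from .preprocess import PreprocessConfig
from .regressor import ModelConfig, TrainConfig
from .synthgen import ParameterRanges

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "read_transform",
    "write_transform",
    "read_manifest",
    "write_manifest",
    "read_config",
    "write_resolved_config",
    "config_hash",
]


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as a uint8 array (grayscale 2-D or RGB 3-D)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB")
            return np.asarray(im)
    except Exception as exc:  # corrupt file: name the path
        raise ValueError(f"cannot read image {path}: {exc}") from exc


def write_image(path, array: np.ndarray) -> None:
    """Write a uint8 array as an image; 8-bit PNG round-trips exactly."""
    arr = np.asarray(array)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(Path(path))


def write_transform(path, t: PolynomialTransform) -> None:
    """Serialize a transform to JSON (or a CSV parameter row for .csv paths).

    JSON stores floats at repr precision, so the round-trip is
    bit-identical.
    """
    path = Path(path)
    if path.suffix == ".csv":
        if not isinstance(t, QuadraticTransform):
            raise ValueError("CSV rows only support quadratic (12-parameter) transforms")
        pd.DataFrame([dict(zip(PARAM_NAMES, t.params))]).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(t.to_dict(), indent=2))


def read_transform(path) -> PolynomialTransform:
    """Read a transform from JSON, or from a CSV row with columns q00..q15."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"transform file not found: {path}")
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        missing = [n for n in PARAM_NAMES if n not in df.columns]
        if missing:
            raise ValueError(f"transform CSV {path} is missing columns {missing}")
        return QuadraticTransform.from_params(df.iloc[0][list(PARAM_NAMES)].to_numpy(float))
    try:
        d = json.loads(path.read_text())
        return PolynomialTransform.from_dict(d)
    except (json.JSONDecodeError, KeyError, ValueError) as exc:
        raise ValueError(f"corrupt transform file {path}: {exc}") from exc


def write_manifest(path, rows: list[dict]) -> None:
    """Write a dataset manifest CSV (fixed_path, moving_path, q00..q15)."""
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    required = ["fixed_path", "moving_path", *PARAM_NAMES]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns {missing}")
    return df


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Composes the preprocessing, model and training settings with the
    parameter ranges and the root seed.  Loading rejects unknown keys;
    omitted keys take the documented defaults (e.g. omega = 0.5).
    """

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    ranges: Optional[ParameterRanges] = None
    seed: int = 0

    def resolved_ranges(self, size: int) -> ParameterRanges:
        return self.ranges if self.ranges is not None else ParameterRanges.default(size)

    def to_dict(self) -> dict:
        d = {
            "preprocess": dataclasses.asdict(self.preprocess),
            "model": dataclasses.asdict(self.model),
            "train": dataclasses.asdict(self.train),
            "seed": self.seed,
        }
        if self.ranges is not None:
            d["ranges"] = self.ranges.to_dict()
        return d


def _build_section(cls, d: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in config section '{section}': {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in d:
            v = d[f.name]
            kwargs[f.name] = tuple(v) if isinstance(v, list) else v
    return cls(**kwargs)


def read_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration, applying defaults for
    omitted keys and rejecting unknown ones."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping at top level")
    known = {"preprocess", "model", "train", "ranges", "seed"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown top-level config key(s) in {path}: {sorted(unknown)}")
    return RunConfig(
        preprocess=_build_section(PreprocessConfig, data.get("preprocess", {}), "preprocess"),
        model=_build_section(ModelConfig, data.get("model", {}), "model"),
        train=_build_section(TrainConfig, data.get("train", {}), "train"),
        ranges=ParameterRanges.from_dict(data["ranges"]) if "ranges" in data else None,
        seed=int(data.get("seed", 0)),
    )


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def write_resolved_config(cfg: RunConfig, out_dir) -> Path:
    """Write the resolved config next to a run's outputs (reproducibility)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "resolved_config.json"
    payload = cfg.to_dict()
    payload["config_hash"] = config_hash(cfg)
    path.write_text(json.dumps(payload, indent=2))
    return path
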