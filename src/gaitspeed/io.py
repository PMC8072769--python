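"""Dataset reading, manifests, run configuration and result writing.

Silhouette sequences live as directories of single-channel PNG/BMP
frames whose lexicographic filename order is the temporal order; any
pixel value above zero is foreground.  A labels manifest (CSV with
header ``sequence_id,directory,label[,participant]``) assigns each
sequence directory a speed class, isolating the pipeline from any
particular dataset's native naming scheme.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .classifier import ModelConfig, TrainingConfig
from .signals import SPEED_CLASSES, WalkingSpeedPattern, pattern_from_dataframe
from .silhouette import (
    DEFAULT_NOISE_FRACTION,
    FEATURE_CSV_COLUMNS,
    BinarySilhouette,
    measure_sequence,
)

__all__ = [
    "read_sequence",
    "read_manifest",
    "extract_patterns",
    "write_features_csv",
    "save_pattern",
    "load_pattern",
    "composition_counts",
    "RunConfig",
]


def composition_counts(
    n_participants: int, sequences_per_class: dict[str, int]
) -> dict[str, int]:
    """Bookkeeping for a cohort-style dataset: one pattern per sequence.

    Given the participant count and the number of recorded sequences per
    speed class per participant, returns the per-class pattern counts and
    the total number of sequences — the arithmetic used to size
    cross-validation plans before any image is read.
    """
    if n_participants <= 0 or any(v < 0 for v in sequences_per_class.values()):
        raise ValueError("participant and sequence counts must be positive")
    per_class = {label: n_participants * v for label, v in sequences_per_class.items()}
    return {
        "total_sequences": sum(per_class.values()),
        **{f"{label}_patterns": v for label, v in per_class.items()},
    }

_IMAGE_SUFFIXES = (".png", ".bmp")


def read_sequence(directory: str | Path) -> list[BinarySilhouette]:
    """Load a silhouette sequence from a directory of PNG/BMP frames.

    Frames are ordered by filename; a frame that fails to load or whose
    dimensions differ from the first frame is an error naming the file,
    never a silent skip.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"sequence directory not found: {directory}")
    files = sorted(
        f for f in directory.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES
    )
    if not files:
        raise ValueError(f"no PNG/BMP frames in {directory}")
    frames: list[BinarySilhouette] = []
    shape: tuple[int, int] | None = None
    for i, f in enumerate(files):
        try:
            with Image.open(f) as img:
                mask = np.asarray(img.convert("L")) > 0
        except Exception as exc:
            raise ValueError(f"unreadable image {f}: {exc}") from exc
        if shape is None:
            shape = mask.shape
        elif mask.shape != shape:
            raise ValueError(
                f"inconsistent frame dimensions: {f} is {mask.shape}, expected {shape}"
            )
        frames.append(BinarySilhouette(mask, frame_index=i))
    return frames


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a labels manifest CSV.

    Checks: required columns present, sequence ids unique, labels drawn
    from the speed classes, and every referenced directory exists and
    contains at least one image.  Relative directories resolve against
    the manifest's location.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"sequence_id", "directory", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {sorted(missing)}")
    if df["sequence_id"].duplicated().any():
        dupes = df.loc[df["sequence_id"].duplicated(), "sequence_id"].tolist()
        raise ValueError(f"duplicate sequence ids in manifest: {dupes}")
    bad = set(df["label"]) - set(SPEED_CLASSES)
    if bad:
        raise ValueError(f"unknown speed labels {sorted(bad)}; expected {SPEED_CLASSES}")
    root = path.parent
    resolved = []
    for d in df["directory"]:
        full = Path(d) if Path(d).is_absolute() else root / d
        if not full.is_dir():
            raise ValueError(f"sequence directory missing: {full}")
        if not any(f.suffix.lower() in _IMAGE_SUFFIXES for f in full.iterdir()):
            raise ValueError(f"sequence directory has no images: {full}")
        resolved.append(str(full))
    out = df.copy()
    out["directory"] = resolved
    return out


def extract_patterns(
    manifest: pd.DataFrame,
    T: int,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    features_dir: str | Path | None = None,
) -> list[WalkingSpeedPattern]:
    """Measure every sequence in a manifest and build its pattern.

    Optionally writes each sequence's per-frame features as CSV into
    ``features_dir`` (columns per :data:`FEATURE_CSV_COLUMNS`).
    """
    patterns = []
    for row in manifest.itertuples(index=False):
        frames = read_sequence(row.directory)
        df = measure_sequence(frames, noise_fraction)
        if features_dir is not None:
            write_features_csv(df, Path(features_dir) / f"{row.sequence_id}.csv")
        patterns.append(
            pattern_from_dataframe(df, row.label, T, source_id=str(row.sequence_id))
        )
    return patterns


def write_features_csv(features: pd.DataFrame, path: str | Path) -> None:
    """Write per-frame measurements + ratios with the canonical header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    features.loc[:, list(FEATURE_CSV_COLUMNS)].to_csv(path, index=False)


def save_pattern(pattern: WalkingSpeedPattern, path: str | Path) -> None:
    """Serialize a pattern: CSV (T rows x 5 columns) + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(pattern.signals.T, columns=["HW1", "HW2", "HW3", "A1", "A2"]).to_csv(
        path, index=False
    )
    sidecar = {"label": pattern.label_name, "source_id": pattern.source_id, "T": pattern.T}
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def load_pattern(path: str | Path) -> WalkingSpeedPattern:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return WalkingSpeedPattern(
        df.to_numpy().T, SPEED_CLASSES.index(meta["label"]), meta["source_id"]
    )


@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    Defaults reproduce the study settings: pattern length 240 (indoor
    style; 35 for the short outdoor sequences), the Table-1-style
    training options, and k = 17 folds.  Serialized as YAML next to every
    command's outputs so runs are self-describing.
    """

    pattern_length: int = 240
    noise_fraction: float = DEFAULT_NOISE_FRACTION
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    cv_method: str = "kfold"  # "kfold" | "random"
    k: int = 17
    n_repeats: int = 272
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        """Load from YAML (JSON is a YAML subset and is accepted too)."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        model = ModelConfig(**raw.pop("model", {}))
        training = TrainingConfig(**raw.pop("training", {}))
        return RunConfig(model=model, training=training, **raw)
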