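"""Readers, writers and run configuration shared by all modules.

The manifest is a CSV with one row per image carrying identity
(patient/visit/eye/modality), the split assignment and per-category Likert
labels; missing labels are empty fields.  Images are loaded into float
arrays in [0, 1] and resized to the model input side with an
aspect-preserving pad (pad value 0), so artefact geometry is never
distorted.  FA files stored as RGB are converted to a single channel by
Rec. 601 luminance.

All randomness in a pipeline flows from one global seed through named
sub-seeds (synth / train / inference), derived here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .categories import ALL_LIKERT_COLUMNS, check_modality

MANIFEST_COLUMNS = (
    "image_path",
    "patient_id",
    "visit_id",
    "eye",
    "modality",
    "split",
) + ALL_LIKERT_COLUMNS

VALID_SPLITS = ("train", "validation", "test")


class ManifestError(ValueError):
    pass


def read_manifest(path: str | Path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a manifest CSV.

    Empty label fields become missing values (pandas NA); Likert entries
    are validated to lie in 1..5, errors cite the row number.  With
    ``check_files`` every referenced image must exist next to the
    manifest.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype={c: "string" for c in MANIFEST_COLUMNS[:6]})
    for col in MANIFEST_COLUMNS:
        if col not in frame.columns:
            raise ManifestError(f"manifest {path} is missing column {col!r}")
    for col in ALL_LIKERT_COLUMNS:
        vals = pd.to_numeric(frame[col], errors="coerce")
        raw_present = frame[col].notna() & (frame[col].astype(str).str.strip() != "")
        bad = raw_present & (vals.isna() | ~vals.isin([1, 2, 3, 4, 5]))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ManifestError(
                f"invalid Likert value {frame[col].iloc[row]!r} in column {col}, "
                f"row {row + 2} of {path}"  # +2: header line and 1-based rows
            )
        frame[col] = vals.astype("Int64")
    bad_split = ~frame["split"].isin(VALID_SPLITS)
    if bad_split.any():
        row = int(np.flatnonzero(bad_split.to_numpy())[0])
        raise ManifestError(f"invalid split {frame['split'].iloc[row]!r} in row {row + 2}")
    if frame["image_path"].duplicated().any():
        dup = frame["image_path"][frame["image_path"].duplicated()].iloc[0]
        raise ManifestError(f"duplicate image_path {dup!r}")
    if check_files:
        for rel in frame["image_path"]:
            if not (path.parent / rel).exists():
                raise ManifestError(f"referenced image missing: {rel}")
    return frame


def write_manifest(frame: pd.DataFrame, path: str | Path) -> None:
    out = frame.loc[:, list(MANIFEST_COLUMNS)].copy()
    out.to_csv(path, index=False)


def read_image(path: str | Path, modality: str, side: int | None = None) -> np.ndarray:
    """Load an image as a float array in [0, 1] with the modality's channels.

    CF gives ``(H, W, 3)``; FA gives ``(H, W, 1)`` (RGB inputs are
    converted by Rec. 601 luminance).  With ``side`` set, the image is
    rescaled to fit a ``side x side`` square preserving aspect ratio and
    centred on a zero pad.
    """
    check_modality(modality)
    try:
        pil = Image.open(path)
        pil.load()
    except Exception as exc:  # noqa: BLE001 - report the offending path
        raise OSError(f"cannot read image {path}: {exc}") from exc
    pil = pil.convert("RGB" if modality == "CF" else "L")
    if side is not None:
        w, h = pil.size
        scale = side / max(w, h)
        new_w = max(1, round(w * scale))
        new_h = max(1, round(h * scale))
        pil = pil.resize((new_w, new_h), Image.BILINEAR)
        canvas = Image.new(pil.mode, (side, side), 0)
        canvas.paste(pil, ((side - new_w) // 2, (side - new_h) // 2))
        pil = canvas
    arr = np.asarray(pil, dtype=np.float64) / 255.0
    if arr.ndim == 2:
        arr = arr[..., None]
    return arr


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class InferenceSection:
    T: int = 16  # stochastic passes per image
    tau: float = 0.5  # per-image decision threshold
    visit_threshold: float = 0.5
    seed: int = 0


@dataclass
class EvaluationSection:
    exclusion_fractions: tuple[float, ...] = (0.1, 0.2, 0.3)
    alpha: float = 0.05


@dataclass
class RunConfig:
    """Fully-resolved pipeline configuration (YAML-backed).

    Every field has a default except the modality.  Sub-seeds for the
    synthesis, training and inference stages are derived from the global
    seed so one integer reproduces the whole pipeline.
    """

    modality: str
    seed: int = 0
    synth: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)
    inference: InferenceSection = field(default_factory=InferenceSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)

    def sub_seed(self, stage: str) -> int:
        """Named, stable sub-seed below 2**31 for one pipeline stage."""
        import zlib

        ss = np.random.SeedSequence(self.seed, spawn_key=(zlib.crc32(stage.encode()),))
        return int(ss.generate_state(1)[0] % 2**31)

    def dataset_config(self):
        from .synthesis import DatasetConfig

        return DatasetConfig(
            modality=self.modality, seed=self.sub_seed("synth"), **self.synth
        )

    def model_config(self):
        from .model import ModelConfig

        kwargs = dict(self.model)
        kwargs.setdefault("seed", self.sub_seed("model"))
        return ModelConfig(modality=self.modality, **kwargs)

    def train_config(self):
        from .model import TrainConfig

        kwargs = dict(self.train)
        kwargs.setdefault("seed", self.sub_seed("train"))
        return TrainConfig(**kwargs)


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"allowed: {sorted(allowed)}"
        )


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config, rejecting unknown keys at every level."""
    from .model import ModelConfig, TrainConfig
    from .synthesis import DatasetConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    _check_keys(
        "top-level", raw, {"modality", "seed", "synth", "model", "train", "inference", "evaluation"}
    )
    if "modality" not in raw:
        raise ValueError("config must set 'modality' (CF or FA)")
    check_modality(raw["modality"])

    def section(name: str, cls) -> dict:
        given = raw.get(name) or {}
        allowed = {f.name for f in fields(cls)} - {"modality", "seed"}
        if cls in (InferenceSection, EvaluationSection):
            allowed = {f.name for f in fields(cls)}
        _check_keys(name, given, allowed)
        return {k: (tuple(v) if isinstance(v, list) else v) for k, v in given.items()}

    cfg = RunConfig(
        modality=raw["modality"],
        seed=int(raw.get("seed", 0)),
        synth=section("synth", DatasetConfig),
        model=section("model", ModelConfig),
        train=section("train", TrainConfig),
        inference=InferenceSection(**section("inference", InferenceSection)),
        evaluation=EvaluationSection(**section("evaluation", EvaluationSection)),
    )
    # echo the fully-resolved configuration for reproducibility
    logging.getLogger("retiqa").info("resolved config from %s: %s", path, cfg)
    return cfg
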