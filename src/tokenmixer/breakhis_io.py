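"""Reading, splitting, resizing and augmenting BreakHis-style image collections.

The on-disk layout mirrors the public breast-cancer histopathology archive:
``root/<magnification>/<subtype>/*.png`` with four magnification strata
(40x/100x/200x/400x), four benign subtypes (AD adenosis-type adenocarcinoma,
FI fibroadenoma, PH phyllodes tumour, TU tubular adenoma) and four malignant
ones (DU ductal, LO lobular, MU mucinous, PA papillary carcinoma).  A manifest
CSV with columns ``path,magnification,subtype`` is accepted interchangeably.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import AffineTransform, resize, warp

__all__ = [
    "BENIGN_SUBTYPES", "MALIGNANT_SUBTYPES", "SUBTYPE_TO_BINARY",
    "MAGNIFICATIONS", "INPUT_SIZE",
    "ImageRecord", "DatasetSplit", "AugmentationConfig",
    "load_records", "stratified_split", "resize_to_input", "augment",
    "write_split_manifest",
]

BENIGN_SUBTYPES = ("AD", "FI", "PH", "TU")
MALIGNANT_SUBTYPES = ("DU", "LO", "MU", "PA")
SUBTYPE_TO_BINARY = {s: "benign" for s in BENIGN_SUBTYPES}
SUBTYPE_TO_BINARY.update({s: "malignant" for s in MALIGNANT_SUBTYPES})
MAGNIFICATIONS = (40, 100, 200, 400)
INPUT_SIZE = 224  # standardized network input side


@dataclass
class ImageRecord:
    """One labelled image; pixels are loaded lazily unless set."""

    path: Path
    magnification: int
    label_subtype: str
    pixels: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.path = Path(self.path)
        if self.label_subtype not in SUBTYPE_TO_BINARY:
            raise ValueError(
                f"unknown subtype {self.label_subtype!r} for {self.path}")
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(
                f"unknown magnification {self.magnification!r} for {self.path}")

    @property
    def label_binary(self) -> str:
        return SUBTYPE_TO_BINARY[self.label_subtype]

    def load_pixels(self, size: int = INPUT_SIZE) -> np.ndarray:
        """8-bit RGB -> float [0, 1], resized to (size, size, 3)."""
        if self.pixels is None:
            with Image.open(self.path) as im:
                arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
            self.pixels = arr
        return resize_to_input(self.pixels, size)


@dataclass
class DatasetSplit:
    train: list[ImageRecord]
    validation: list[ImageRecord]
    test: list[ImageRecord]
    seed: int
    ratios: tuple[float, float, float] = (0.64, 0.16, 0.20)

    def __iter__(self):
        yield from (("train", self.train), ("val", self.validation),
                    ("test", self.test))


@dataclass
class AugmentationConfig:
    """Geometric augmentation ranges (training-time, on-the-fly).

    Defaults are the study's settings: rotations within +/-5 degrees, width
    and height shifts within +/-10% and zoom within +/-0.1%.  The fill policy
    for exposed borders defaults to ``nearest`` (edge replication).
    """

    rotation_range_deg: float = 5.0
    width_shift_frac: float = 0.1
    height_shift_frac: float = 0.1
    zoom_range: float = 0.001
    fill_mode: str = "nearest"

    def __post_init__(self):
        for name in ("rotation_range_deg", "width_shift_frac",
                     "height_shift_frac", "zoom_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fill_mode not in ("nearest", "reflect", "constant"):
            raise ValueError(f"invalid fill_mode {self.fill_mode!r}")

    @classmethod
    def none(cls) -> "AugmentationConfig":
        return cls(0.0, 0.0, 0.0, 0.0, "nearest")


def load_records(root_or_manifest: str | Path,
                 layout: str | None = None) -> list[ImageRecord]:
    """Collect :class:`ImageRecord` from a directory tree or a manifest CSV.

    ``layout`` is ``"directory"`` or ``"manifest"``; when omitted it is
    inferred (a CSV file is a manifest, a directory is a tree).
    """
    src = Path(root_or_manifest)
    if layout is None:
        layout = "manifest" if src.is_file() else "directory"
    if layout == "manifest":
        df = pd.read_csv(src)
        missing = {"path", "magnification", "subtype"} - set(df.columns)
        if missing:
            raise ValueError(f"manifest {src} lacks columns {sorted(missing)}")
        base = src.parent
        records = []
        for row in df.itertuples(index=False):
            p = Path(row.path)
            if not p.is_absolute():
                p = base / p
            records.append(ImageRecord(p, int(row.magnification), str(row.subtype)))
    elif layout == "directory":
        if not src.is_dir():
            raise FileNotFoundError(src)
        records = []
        for mag_dir in sorted(src.iterdir()):
            if not mag_dir.is_dir() or not mag_dir.name.isdigit():
                continue
            mag = int(mag_dir.name)
            for sub_dir in sorted(mag_dir.iterdir()):
                if not sub_dir.is_dir():
                    continue
                for f in sorted(sub_dir.glob("*")):
                    if f.suffix.lower() in (".png", ".jpg", ".jpeg"):
                        records.append(ImageRecord(f, mag, sub_dir.name))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    if not records:
        raise ValueError(f"no images found under {src}")
    return records


def _labels(records: list[ImageRecord], by: str) -> list[str]:
    if by == "binary":
        return [r.label_binary for r in records]
    if by == "subtype":
        return [r.label_subtype for r in records]
    raise ValueError(f"unknown label kind {by!r}")


def stratified_split(records: list[ImageRecord], seed: int,
                     by: str = "binary") -> DatasetSplit:
    """Deterministic stratified 64/16/20 train/validation/test split.

    The test fraction (20%) is sliced first, then 20% of the remainder
    becomes validation; both use floor rounding per class with the remainder
    assigned to training.  Within each class the order is shuffled by
    ``seed``, so the same (records, seed) pair always yields the same split.
    """
    labels = _labels(records, by)
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    train_idx, val_idx, test_idx = [], [], []
    for lab in sorted(by_class):
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        n = len(idx)
        n_test = int(np.floor(0.2 * n))
        n_val = int(np.floor(0.2 * (n - n_test)))
        if n_test < 1 or n_val < 1:
            raise ValueError(
                f"class {lab!r} has only {n} records; stratification across "
                "train/validation/test requires at least 6 per class")
        test_idx.extend(idx[:n_test])
        val_idx.extend(idx[n_test:n_test + n_val])
        train_idx.extend(idx[n_test + n_val:])
    return DatasetSplit(
        train=[records[i] for i in sorted(train_idx)],
        validation=[records[i] for i in sorted(val_idx)],
        test=[records[i] for i in sorted(test_idx)],
        seed=seed,
    )


def resize_to_input(image: np.ndarray, size: int = INPUT_SIZE) -> np.ndarray:
    """Bilinear resize to (size, size, 3), preserving the [0, 1] range."""
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) input, got {image.shape}")
    if image.shape[:2] == (size, size):
        return image
    out = resize(image, (size, size, 3), order=1, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


_FILL_TO_SKIMAGE = {"nearest": "edge", "reflect": "reflect", "constant": "constant"}


def augment(image: np.ndarray, config: AugmentationConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Random rotation / shift / zoom within the configured ranges.

    The transform is sampled from ``rng`` (deterministic given its state) and
    applied with bilinear interpolation about the image centre; output shape
    and the [0, 1] value range are preserved.
    """
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape[:2]
    angle = np.deg2rad(rng.uniform(-config.rotation_range_deg,
                                   config.rotation_range_deg))
    tx = rng.uniform(-config.width_shift_frac, config.width_shift_frac) * w
    ty = rng.uniform(-config.height_shift_frac, config.height_shift_frac) * h
    zoom = 1.0 + rng.uniform(-config.zoom_range, config.zoom_range)
    if angle == 0.0 and tx == 0.0 and ty == 0.0 and zoom == 1.0:
        return image
    centre = np.array([w / 2.0, h / 2.0])
    tf = (AffineTransform(translation=-centre)
          + AffineTransform(rotation=angle, scale=(zoom, zoom))
          + AffineTransform(translation=centre)
          + AffineTransform(translation=(tx, ty)))
    out = warp(image, tf.inverse, order=1,
               mode=_FILL_TO_SKIMAGE[config.fill_mode], cval=0.0,
               preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def write_split_manifest(split: DatasetSplit, out_csv: str | Path) -> Path:
    """Persist a split as a manifest CSV with an added ``split`` column."""
    out_csv = Path(out_csv)
    with open(out_csv, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "magnification", "subtype", "split"])
        for name, recs in split:
            for r in recs:
                writer.writerow([str(r.path), r.magnification,
                                 r.label_subtype, name])
    return out_csv
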