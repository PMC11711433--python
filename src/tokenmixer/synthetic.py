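"""Seeded, class-separable synthetic histology-like image generation.

Each subtype is a distinct texture process: a Gaussian-noise background
around a subtype-specific base colour, plus Poisson-many elliptical "nuclei"
blobs with subtype-specific density, radius and hue.  Magnification is
emulated by scaling blob radii with the objective power and blurring the two
lowest strata, so the four strata have distinct image statistics without any
claim to histological realism.

The default per-(magnification, subtype) counts are the published archive's
counts divided by 10 (rounded up), preserving the benign:malignant imbalance
direction; images are drawn at 460 x 700 (H x W) so the resize path is
exercised with a realistic aspect ratio.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

from .breakhis_io import MAGNIFICATIONS, SUBTYPE_TO_BINARY

__all__ = ["SubtypeTexture", "SyntheticSpec", "generate_dataset",
           "make_toy_tensors", "DEFAULT_COUNTS"]


# archive per-subtype counts at (40x, 100x, 200x, 400x), divided by 10, ceil
_FULL_COUNTS = {
    "AD": (114, 113, 111, 106),
    "FI": (253, 260, 264, 253),
    "PH": (109, 121, 108, 115),
    "TU": (149, 150, 140, 130),
    "DU": (864, 903, 896, 788),
    "LO": (156, 170, 163, 137),
    "MU": (205, 222, 196, 169),
    "PA": (145, 142, 135, 138),
}
DEFAULT_COUNTS: dict[tuple[int, str], int] = {
    (mag, sub): math.ceil(c / 10)
    for sub, counts in _FULL_COUNTS.items()
    for mag, c in zip((40, 100, 200, 400), counts)
}


@dataclass
class SubtypeTexture:
    """Texture parameters for one subtype."""

    base_hue: tuple[float, float, float]   # background RGB in [0, 1]
    blob_hue: tuple[float, float, float]   # nucleus RGB in [0, 1]
    blob_density: float                    # expected blobs per 10^4 px^2
    blob_radius_mean: float                # px at 40x
    blob_radius_sd: float
    noise_sd: float                        # background Gaussian noise sd


def _default_textures() -> dict[str, SubtypeTexture]:
    # hues spread over the RGB cube so any two subtypes differ by >= 0.3
    # in euclidean distance; benign subtypes lean pink, malignant purple/blue,
    # echoing the look of haematoxylin-eosin staining without modelling it.
    hues = {
        "AD": (0.93, 0.72, 0.80), "FI": (0.85, 0.55, 0.45),
        "PH": (0.95, 0.88, 0.60), "TU": (0.70, 0.85, 0.70),
        "DU": (0.55, 0.35, 0.65), "LO": (0.40, 0.45, 0.85),
        "MU": (0.35, 0.65, 0.75), "PA": (0.60, 0.30, 0.35),
    }
    blob = {
        "AD": (0.55, 0.25, 0.45), "FI": (0.50, 0.20, 0.20),
        "PH": (0.60, 0.50, 0.25), "TU": (0.30, 0.50, 0.35),
        "DU": (0.25, 0.10, 0.35), "LO": (0.15, 0.18, 0.50),
        "MU": (0.10, 0.35, 0.45), "PA": (0.30, 0.10, 0.15),
    }
    dens = {"AD": 0.8, "FI": 1.2, "PH": 0.6, "TU": 1.0,
            "DU": 1.6, "LO": 1.1, "MU": 0.7, "PA": 1.4}
    rad = {"AD": 5.0, "FI": 6.0, "PH": 7.0, "TU": 4.5,
           "DU": 5.5, "LO": 4.0, "MU": 6.5, "PA": 5.0}
    return {
        s: SubtypeTexture(base_hue=hues[s], blob_hue=blob[s], blob_density=dens[s],
                          blob_radius_mean=rad[s], blob_radius_sd=rad[s] * 0.2,
                          noise_sd=0.03)
        for s in SUBTYPE_TO_BINARY
    }


@dataclass
class SyntheticSpec:
    """Full description of a synthetic dataset; (spec, seed) fixes every byte."""

    subtypes: dict[str, SubtypeTexture] = field(default_factory=_default_textures)
    counts: dict[tuple[int, str], int] = field(
        default_factory=lambda: dict(DEFAULT_COUNTS))
    image_size: tuple[int, int] = (460, 700)   # (H, W) before resize
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be >= 0")
        for name, t in self.subtypes.items():
            if min(t.base_hue + t.blob_hue) < 0 or max(t.base_hue + t.blob_hue) > 1:
                raise ValueError(f"hue out of [0,1] for subtype {name}")
            if t.blob_density < 0 or t.blob_radius_sd < 0 or t.noise_sd < 0:
                raise ValueError(f"negative texture parameter for subtype {name}")
        seen = {}
        for name, t in self.subtypes.items():
            key = (t.base_hue, t.blob_hue, t.blob_density, t.blob_radius_mean)
            if key in seen:
                raise ValueError(
                    f"subtypes {seen[key]} and {name} have identical textures")
            seen[key] = name

    # -- YAML round trip ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "image_size": list(self.image_size),
            "subtypes": {
                n: {"base_hue": list(t.base_hue), "blob_hue": list(t.blob_hue),
                    "blob_density": t.blob_density,
                    "blob_radius_mean": t.blob_radius_mean,
                    "blob_radius_sd": t.blob_radius_sd, "noise_sd": t.noise_sd}
                for n, t in self.subtypes.items()},
            "counts": [{"magnification": m, "subtype": s, "count": c}
                       for (m, s), c in sorted(self.counts.items())],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        doc = yaml.safe_load(Path(path).read_text())
        subtypes = {
            n: SubtypeTexture(base_hue=tuple(d["base_hue"]),
                              blob_hue=tuple(d["blob_hue"]),
                              blob_density=float(d["blob_density"]),
                              blob_radius_mean=float(d["blob_radius_mean"]),
                              blob_radius_sd=float(d["blob_radius_sd"]),
                              noise_sd=float(d["noise_sd"]))
            for n, d in doc["subtypes"].items()}
        counts = {(int(e["magnification"]), e["subtype"]): int(e["count"])
                  for e in doc["counts"]}
        return cls(subtypes=subtypes, counts=counts,
                   image_size=tuple(doc["image_size"]), seed=int(doc["seed"]))


def _render_image(texture: SubtypeTexture, magnification: int,
                  size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = size
    img = np.empty((h, w, 3), dtype=np.float32)
    for c in range(3):
        img[..., c] = texture.base_hue[c]
    img += rng.normal(0.0, texture.noise_sd, size=(h, w, 3)).astype(np.float32)

    # nuclei: Poisson count at the configured density, uniform positions
    lam = texture.blob_density * (h * w) / 1e4
    n_blobs = rng.poisson(lam)
    scale = magnification / 40.0  # radii grow with objective power
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = max(1.5, rng.normal(texture.blob_radius_mean * scale,
                                texture.blob_radius_sd * scale))
        aspect = rng.uniform(0.6, 1.0)
        theta = rng.uniform(0, np.pi)
        # rasterize only inside the blob's bounding box
        y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 2)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask = (u / r) ** 2 + (v / (r * aspect)) ** 2 <= 1.0
        region = img[y0:y1, x0:x1]
        for c in range(3):
            region[..., c][mask] = texture.blob_hue[c]

    if magnification <= 100:  # low power: slight optical blur
        sigma = 1.5 if magnification == 40 else 0.8
        img = gaussian_filter(img, sigma=(sigma, sigma, 0))
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write the dataset as PNGs under ``<magnification>/<subtype>/`` + manifest.

    Returns the manifest DataFrame (columns ``path,magnification,subtype``;
    paths relative to ``out_dir``).  Identical (spec, seed) produce
    byte-identical files.
    """
    if sum(spec.counts.values()) == 0:
        raise ValueError("spec requests zero images")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (mag, sub) in sorted(spec.counts):
        count = spec.counts[(mag, sub)]
        if count == 0:
            continue
        if sub not in spec.subtypes:
            raise ValueError(f"no texture defined for subtype {sub!r}")
        if mag not in MAGNIFICATIONS:
            raise ValueError(f"unknown magnification {mag!r}")
        sub_dir = out_dir / str(mag) / sub
        sub_dir.mkdir(parents=True, exist_ok=True)
        # independent stream per (mag, subtype) so counts don't interact;
        # crc32 is stable across processes, unlike builtin hash()
        rng = np.random.default_rng([spec.seed, mag, zlib.crc32(sub.encode())])
        for i in range(count):
            img = _render_image(spec.subtypes[sub], mag, spec.image_size, rng)
            arr = (img * 255.0).round().astype(np.uint8)
            rel = Path(str(mag)) / sub / f"{sub}_{mag}x_{i:04d}.png"
            Image.fromarray(arr).save(out_dir / rel)
            rows.append({"path": str(rel), "magnification": mag, "subtype": sub})
    manifest = pd.DataFrame(rows, columns=["path", "magnification", "subtype"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    spec.to_yaml(out_dir / "spec.yaml")
    return manifest


def make_toy_tensors(shape: tuple[int, int, int, int], seed: int) -> np.ndarray:
    """I.i.d. uniform [0, 1] rank-4 test fixtures, deterministic per seed."""
    if len(shape) != 4 or any(int(d) < 1 for d in shape):
        raise ValueError(f"all four dims must be >= 1, got {shape}")
    return np.random.default_rng(seed).random(shape, dtype=np.float64).reshape(shape)
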