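"""Shared fixtures: in-memory record sets and a small generated dataset."""

from __future__ import annotations

import numpy as np
import pytest

from tokenmixer.breakhis_io import ImageRecord
from tokenmixer.synthetic import SyntheticSpec, generate_dataset


def make_records(counts: dict[tuple[int, str], int],
                 size: tuple[int, int] = (32, 32),
                 seed: int = 0) -> list[ImageRecord]:
    """Fabricate in-memory records (no files) with subtype-tinted pixels."""
    rng = np.random.default_rng(seed)
    records = []
    for (mag, sub), n in sorted(counts.items()):
        for i in range(n):
            base = (rng.random(3) * 0.5 + 0.25).astype(np.float32)
            px = np.clip(base + rng.normal(0, 0.05, (*size, 3)), 0, 1)
            records.append(ImageRecord(
                path=f"mem/{mag}/{sub}/{i}.png", magnification=mag,
                label_subtype=sub, pixels=px.astype(np.float32)))
    return records


@pytest.fixture(scope="session")
def separable_dataset(tmp_path_factory):
    """Two well-separated subtypes, 100 images each, at one magnification.

    Session-scoped because generation is the slow part; the directory holds
    a manifest plus PNGs in the standard layout.
    """
    out = tmp_path_factory.mktemp("separable")
    spec = SyntheticSpec(counts={(200, "FI"): 100, (200, "DU"): 100}, seed=7)
    manifest = generate_dataset(spec, out)
    return out, manifest


@pytest.fixture(scope="session")
def small_tree(tmp_path_factory):
    """A tiny multi-subtype dataset on disk (for IO and CLI tests)."""
    out = tmp_path_factory.mktemp("smalltree")
    counts = {(40, s): 3 for s in ("FI", "DU")}
    counts.update({(200, s): 2 for s in ("AD", "MU")})
    spec = SyntheticSpec(counts=counts, image_size=(46, 70), seed=3)
    manifest = generate_dataset(spec, out)
    return out, manifest
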