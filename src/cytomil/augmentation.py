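"""Four-variant patch augmentation: original, two flips, colour jitter.

Every patch expands into exactly four images — the original, its horizontal
mirror, its vertical mirror, and one colour-jittered copy — so the dataset
grows by a fixed factor of 4 and the class composition is conserved exactly
(each variant inherits its source's slide and labels).  Flips are
pixel-exact index reversals; jitter draws one factor per property
(brightness, contrast, saturation) uniformly from ``[1 - a, 1 + a]``,
deterministically from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .records import PatchRecord
from .seeding import substream

AUG_VARIANTS = ("o", "h", "v", "j")
AUG_FACTOR = len(AUG_VARIANTS)


@dataclass
class AugmentConfig:
    jitter_brightness: float = 0.1
    jitter_contrast: float = 0.1
    jitter_saturation: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("jitter_brightness", "jitter_contrast", "jitter_saturation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def hflip(img: np.ndarray) -> np.ndarray:
    """Mirror columns (left-right), pixel-exact."""
    return np.ascontiguousarray(img[:, ::-1])


def vflip(img: np.ndarray) -> np.ndarray:
    """Mirror rows (top-bottom), pixel-exact."""
    return np.ascontiguousarray(img[::-1])


def color_jitter(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """Brightness/contrast/saturation jitter with factors ~ U[1-a, 1+a].

    With all amplitudes 0 the output equals the input exactly.  Output dtype
    matches the input; uint8 values are clipped to [0, 255].
    """
    b = rng.uniform(1 - cfg.jitter_brightness, 1 + cfg.jitter_brightness)
    c = rng.uniform(1 - cfg.jitter_contrast, 1 + cfg.jitter_contrast)
    s = rng.uniform(1 - cfg.jitter_saturation, 1 + cfg.jitter_saturation)
    if cfg.jitter_brightness == cfg.jitter_contrast == cfg.jitter_saturation == 0:
        return img.copy()
    out = img.astype(np.float64)
    out = out * b
    out = out.mean() + c * (out - out.mean())
    gray = out.mean(axis=2, keepdims=True)
    out = gray + s * (out - gray)
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return out.astype(img.dtype)


def augment_patch(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """The four augmentation variants of one patch image, in o/h/v/j order."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"expected a square patch, got shape {img.shape}")
    if rng is None:
        rng = substream(cfg.seed, "jitter")
    return [img.copy(), hflip(img), vflip(img), color_jitter(img, cfg, rng)]


def augment_dataset(patches: Sequence[PatchRecord], cfg: AugmentConfig) -> list[PatchRecord]:
    """Expand in-memory patches 4x; each variant inherits slide_id and labels."""
    rng = substream(cfg.seed, "jitter")
    out: list[PatchRecord] = []
    for p in patches:
        if p.pixels is None:
            raise ValueError(f"patch ({p.slide_id}, {p.row}, {p.col}) has no pixel data; use augment_manifest for record-only expansion")
        for variant, img in zip(AUG_VARIANTS, augment_patch(p.pixels, cfg, rng)):
            out.append(replace(p, pixels=img, aug=variant))
    return out


def augment_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Record-level (pixel-free) 4x expansion of a patch manifest.

    This is the counting path of the augmentation stage: each manifest row
    is repeated once per variant and tagged in an ``aug`` column, so
    dataset-size and class-composition bookkeeping can be done on millions
    of rows without touching pixels.
    """
    out = manifest.loc[manifest.index.repeat(AUG_FACTOR)].reset_index(drop=True)
    out["aug"] = np.tile(np.array(AUG_VARIANTS), len(manifest))
    return out


def augmented_path(path: str, variant: str) -> str:
    """Filename for an augmented variant: ``x.png`` -> ``x_h.png`` etc."""
    from pathlib import Path

    p = Path(path)
    return str(p.with_name(f"{p.stem}_{variant}{p.suffix}"))
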