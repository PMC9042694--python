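"""Tile whole-slide rasters into non-overlapping patches; manifest I/O.

Patches are fixed-size squares cut on a regular grid: patch (r, c) covers
pixel rows ``[r*patch_px, (r+1)*patch_px)`` and the analogous columns
(0-based, half-open), enumerated row-major.  Remainder strips that do not
fit a full patch are discarded by default.  Patches destined for the
classifier are downscaled with bilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .records import PatchRecord, SlideRecord

MANIFEST_COLUMNS = ["slide_id", "weak_label", "split", "row", "col", "path", "instance_truth"]


@dataclass
class TilingConfig:
    """Tiling geometry and model input size.

    ``patch_px`` is the crop size taken from the raster, ``model_px`` the
    side length patches are resized to before scoring.  ``background_filter``
    is ``"none"`` or ``"mean_intensity"``; the latter drops patches whose
    mean intensity exceeds ``background_threshold`` (blank glass is bright).
    """

    patch_px: int = 512
    model_px: int = 256
    keep_partial_edges: bool = False
    background_filter: str = "none"
    background_threshold: float = 240.0

    def __post_init__(self) -> None:
        if not self.patch_px >= self.model_px >= 8:
            raise ValueError(f"need patch_px >= model_px >= 8, got {self.patch_px}, {self.model_px}")
        if self.background_filter not in ("none", "mean_intensity"):
            raise ValueError(f"unknown background_filter {self.background_filter!r}")


def tile_slide(image: np.ndarray, cfg: TilingConfig, slide_id: str = "slide") -> list[PatchRecord]:
    """Crop ``image`` (H x W x 3) into non-overlapping ``patch_px`` squares.

    Returns ``floor(H/patch_px) * floor(W/patch_px)`` patches in row-major
    order (plus partial edge tiles if ``keep_partial_edges``).  Patch pixel
    data are views copied out of the input; footprints are pairwise disjoint
    and their union is the cropped region.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 raster, got shape {image.shape}")
    h, w = image.shape[:2]
    p = cfg.patch_px
    if h < p or w < p:
        raise ValueError(f"image {h}x{w} is smaller than one {p}x{p} patch")

    n_rows, n_cols = h // p, w // p
    if cfg.keep_partial_edges:
        n_rows += int(h % p > 0)
        n_cols += int(w % p > 0)

    patches = []
    for r in range(n_rows):
        for c in range(n_cols):
            tile = image[r * p : (r + 1) * p, c * p : (c + 1) * p]
            if cfg.background_filter == "mean_intensity" and tile.mean() > cfg.background_threshold:
                continue
            patches.append(PatchRecord(slide_id=slide_id, row=r, col=c, pixels=tile.copy()))
    return patches


def resize_patch(patch: PatchRecord | np.ndarray, model_px: int) -> np.ndarray:
    """Bilinear resize of a square patch to ``model_px`` a side.

    Identity (pixel-exact) when the patch is already ``model_px``; dtype and
    value range are preserved.
    """
    img = patch.pixels if isinstance(patch, PatchRecord) else np.asarray(patch)
    if img is None:
        raise ValueError("patch has no pixel data")
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"patch must be square, got shape {img.shape}")
    if img.shape[0] == model_px:
        return img.copy()
    dtype = img.dtype
    if img.ndim == 3:
        out = np.asarray(Image.fromarray(np.ascontiguousarray(img)).resize((model_px, model_px), Image.BILINEAR))
    else:
        out = np.asarray(Image.fromarray(np.ascontiguousarray(img), mode="L").resize((model_px, model_px), Image.BILINEAR))
    return out.astype(dtype, copy=False)


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF raster as an array (tifffile for .tif, Pillow otherwise)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    return np.asarray(Image.open(path).convert("RGB") if path.suffix.lower() != ".png" else Image.open(path))


def mean_patches_per_slide(n_patches: int, n_slides: int) -> int:
    """Average patch count per slide, reported to the nearest integer."""
    if n_slides <= 0:
        raise ValueError("n_slides must be positive")
    from decimal import ROUND_HALF_UP, Decimal

    return int((Decimal(n_patches) / Decimal(n_slides)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def write_manifest(slides: Sequence[SlideRecord], path: str | Path) -> None:
    """Write slides as a TSV manifest (unknown instance_truth -> "NA")."""
    rows = []
    for s in slides:
        for p in s.patches:
            rows.append(
                {
                    "slide_id": s.slide_id,
                    "weak_label": s.weak_label,
                    "split": s.split if s.split is not None else "NA",
                    "row": p.row,
                    "col": p.col,
                    "path": p.path if p.path is not None else "NA",
                    "instance_truth": p.instance_truth if p.instance_truth is not None else "NA",
                }
            )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[SlideRecord]:
    """Read a TSV manifest back into SlideRecords (round-trip inverse of
    :func:`write_manifest`; pixel data are not loaded)."""
    df = pd.read_csv(path, sep="\t", dtype={"slide_id": str}, keep_default_na=False, na_values=[])
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing required column(s): {', '.join(missing)}")
    dup_mask = df.duplicated(subset=["slide_id", "row", "col"], keep=False)
    if dup_mask.any():
        # +2: 1-based line numbers counting the header
        lines = [str(i + 2) for i in df.index[dup_mask]]
        raise ValueError(f"manifest {path} has duplicate (slide_id, row, col) at line(s) {', '.join(lines)}")

    slides: dict[str, SlideRecord] = {}
    order: list[str] = []
    for rec in df.itertuples(index=False):
        sid = str(rec.slide_id)
        truth = None if str(rec.instance_truth) == "NA" else int(rec.instance_truth)
        split = None if str(rec.split) == "NA" else str(rec.split)
        p_path = None if str(rec.path) == "NA" else str(rec.path)
        patch = PatchRecord(sid, int(rec.row), int(rec.col), path=p_path, instance_truth=truth)
        if sid not in slides:
            slides[sid] = SlideRecord(sid, int(rec.weak_label), [], split=split)
            order.append(sid)
        slides[sid].patches.append(patch)
    # re-validate per-slide uniqueness invariants
    return [SlideRecord(slides[s].slide_id, slides[s].weak_label, slides[s].patches, slides[s].split) for s in order]


def load_patch_pixels(patch: PatchRecord) -> np.ndarray:
    """Pixel data of a patch, reading from ``path`` when not in memory."""
    if patch.pixels is not None:
        return patch.pixels
    if patch.path is None:
        raise ValueError(f"patch ({patch.slide_id}, {patch.row}, {patch.col}) has neither pixels nor a path")
    try:
        return read_image(patch.path)
    except Exception as exc:  # noqa: BLE001 - re-raise with patch identity
        raise ValueError(f"patch image unreadable: {patch.path} ({exc})") from exc
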