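"""Synthetic slide datasets with known slide- and patch-level ground truth.

Real cytology slides are private; every downstream stage is instead
exercised on synthetic slides built as grids of patches.  A benign patch is
a bright, lightly textured field (emulating the thin cell layer of a
liquid-based preparation); a malignant patch additionally carries a motif of
large dark elliptical clusters, standing in for the enlarged, hyperchromatic
tumour-cell clusters a cytopathologist keys on.  The motif is deliberately
simple: any visually separable texture exercises the multiple-instance
mechanics (weak labels, ranking, top-k selection, thresholded aggregation)
identically, and the generator's job is to make instance-level ground truth
available, not to be photorealistic.

The weak-label premise is built in: a benign slide contains *zero*
motif-bearing patches, a malignant slide contains at least one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.draw import ellipse

from .records import PatchRecord, SlideRecord, VALID_SPLITS
from .seeding import substream

#: Mean RGB of the benign background field (H&E-like pale violet-grey).
BACKGROUND_RGB = (208.0, 198.0, 214.0)
#: Peak intensity drop of a motif cluster relative to background, scaled by
#: ``motif_contrast``.
MOTIF_DEPTH = 150.0


@dataclass
class SynthConfig:
    """Parameters of the synthetic slide generator.

    Parameters
    ----------
    n_slides_malignant, n_slides_benign
        Number of slides of each class.
    grid_rows, grid_cols
        Patch grid of every slide; the bag size is ``grid_rows * grid_cols``.
    patch_px
        Side length of each generated patch in pixels.
    pos_patch_fraction
        Fraction of patches in a malignant slide that carry the malignant
        motif, in (0, 1].  Real positivity rates are unknown; this is an
        exploration knob.
    motif_contrast
        In (0, 1]; scales the intensity drop of the motif clusters below the
        background.  Larger values make instances easier to separate.
    noise_sd
        Standard deviation of the per-pixel Gaussian texture noise, in
        8-bit intensity units.
    seed
        Root seed; generation is fully reproducible.
    """

    n_slides_malignant: int = 18
    n_slides_benign: int = 18
    grid_rows: int = 8
    grid_cols: int = 8
    patch_px: int = 512
    pos_patch_fraction: float = 0.2
    motif_contrast: float = 0.6
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slides_malignant < 0 or self.n_slides_benign < 0:
            raise ValueError("slide counts must be non-negative")
        if self.grid_rows * self.grid_cols < 1:
            raise ValueError("grid must contain at least one patch")
        if not 0.0 < self.pos_patch_fraction <= 1.0:
            raise ValueError(f"pos_patch_fraction must lie in (0, 1], got {self.pos_patch_fraction}")
        if not 0.0 < self.motif_contrast <= 1.0:
            raise ValueError(f"motif_contrast must lie in (0, 1], got {self.motif_contrast}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.patch_px < 8:
            raise ValueError("patch_px must be >= 8")

    @property
    def n_pos_patches(self) -> int:
        """Motif-bearing patches per malignant slide (round to nearest)."""
        return round(self.pos_patch_fraction * self.grid_rows * self.grid_cols)


def _background_patch(px: int, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Bright textured field: base colour + low-frequency blotch + noise."""
    base = np.empty((px, px, 3), dtype=np.float64)
    base[:] = BACKGROUND_RGB
    # low-frequency illumination blotch, shared across channels
    n_coarse = max(2, px // 16)
    coarse = rng.normal(0.0, 6.0, size=(n_coarse, n_coarse))
    reps = math.ceil(px / n_coarse)
    blotch = np.kron(coarse, np.ones((reps, reps)))[:px, :px]
    base += blotch[:, :, None]
    if noise_sd > 0:
        base += rng.normal(0.0, noise_sd, size=base.shape)
    return base


def _stamp_motif(img: np.ndarray, contrast: float, rng: np.random.Generator) -> None:
    """Stamp dark elliptical 'cell cluster' blobs into ``img`` in place."""
    px = img.shape[0]
    n_blobs = int(rng.integers(3, 7))
    depth = contrast * MOTIF_DEPTH
    for _ in range(n_blobs):
        r_c = rng.uniform(0.15 * px, 0.85 * px)
        c_c = rng.uniform(0.15 * px, 0.85 * px)
        r_rad = rng.uniform(0.10 * px, 0.22 * px)
        c_rad = rng.uniform(0.10 * px, 0.22 * px)
        rot = rng.uniform(0.0, np.pi)
        rr, cc = ellipse(r_c, c_c, r_rad, c_rad, shape=img.shape[:2], rotation=rot)
        # dark violet nucleus-like tint: strongest drop in green
        img[rr, cc, 0] -= 0.9 * depth
        img[rr, cc, 1] -= depth
        img[rr, cc, 2] -= 0.7 * depth


def render_patch(cfg: SynthConfig, malignant: bool, rng: np.random.Generator) -> np.ndarray:
    """Render one patch as ``patch_px x patch_px x 3`` uint8."""
    img = _background_patch(cfg.patch_px, cfg.noise_sd, rng)
    if malignant:
        _stamp_motif(img, cfg.motif_contrast, rng)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_dataset(cfg: SynthConfig) -> list[SlideRecord]:
    """Generate ``n_slides_malignant + n_slides_benign`` synthetic slides.

    Each malignant slide has exactly ``round(pos_patch_fraction * grid_rows
    * grid_cols)`` motif-bearing patches (``instance_truth == 1``) at random
    grid positions; benign slides have none.  Byte-identical output for
    identical config (including seed).

    Raises
    ------
    ValueError
        If ``pos_patch_fraction`` rounds to zero positive patches while
        malignant slides are requested.
    """
    n_pos = cfg.n_pos_patches
    if cfg.n_slides_malignant > 0 and n_pos < 1:
        raise ValueError(
            f"pos_patch_fraction={cfg.pos_patch_fraction} rounds to 0 positive patches "
            f"on a {cfg.grid_rows}x{cfg.grid_cols} grid; a malignant slide must contain at least one"
        )
    rng = substream(cfg.seed, "synth")
    n_cells = cfg.grid_rows * cfg.grid_cols
    slides: list[SlideRecord] = []
    labels = [1] * cfg.n_slides_malignant + [0] * cfg.n_slides_benign
    for i, label in enumerate(labels):
        slide_id = f"{'mal' if label else 'ben'}_{i:04d}"
        if label:
            pos_cells = set(rng.choice(n_cells, size=n_pos, replace=False).tolist())
        else:
            pos_cells = set()
        patches = []
        for cell in range(n_cells):
            r, c = divmod(cell, cfg.grid_cols)
            truth = int(cell in pos_cells)
            patches.append(
                PatchRecord(
                    slide_id=slide_id,
                    row=r,
                    col=c,
                    pixels=render_patch(cfg, bool(truth), rng),
                    instance_truth=truth,
                )
            )
        slides.append(SlideRecord(slide_id=slide_id, weak_label=label, patches=patches))
    return slides


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of ``n`` items to ``fractions`` (sums exactly to n)."""
    quotas = [n * f for f in fractions]
    sizes = [math.floor(q) for q in quotas]
    shortfall = n - sum(sizes)
    # hand the remaining items to the largest fractional remainders;
    # ties broken by position for determinism
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:shortfall]:
        sizes[i] += 1
    return sizes


def split_dataset(
    slides: Sequence[SlideRecord],
    fractions: tuple[float, float, float],
    seed: int,
    require_both_classes: bool = True,
) -> list[SlideRecord]:
    """Randomly allocate slides to train/validation/test, stratified by label.

    Split sizes follow the largest-remainder rounding of ``fractions``
    within each class, so per-split class proportions deviate from the
    overall proportion by at most one slide.  Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If fractions do not sum to 1, or (when ``require_both_classes``)
        a non-empty split would receive zero slides of one class while both
        classes exist in the input.
    """
    if len(fractions) != 3:
        raise ValueError("fractions must be (train, validation, test)")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")

    rng = substream(seed, "split")
    by_class: dict[int, list[SlideRecord]] = {0: [], 1: []}
    for s in slides:
        by_class[s.weak_label].append(s)

    assignment: dict[str, str] = {}
    alloc: dict[int, list[int]] = {}
    for label in (0, 1):
        group = by_class[label]
        if not group:
            continue
        sizes = _largest_remainder(len(group), fractions)
        alloc[label] = sizes
        perm = rng.permutation(len(group))
        cursor = 0
        for split_name, size in zip(VALID_SPLITS, sizes):
            for j in perm[cursor : cursor + size]:
                assignment[group[j].slide_id] = split_name
            cursor += size

    both_classes = bool(by_class[0]) and bool(by_class[1])
    if require_both_classes and both_classes:
        for k, split_name in enumerate(VALID_SPLITS):
            total = alloc[0][k] + alloc[1][k]
            if total > 0 and (alloc[0][k] == 0 or alloc[1][k] == 0):
                raise ValueError(
                    f"split {split_name!r} would receive zero slides of one class "
                    f"(benign={alloc[0][k]}, malignant={alloc[1][k]}); "
                    "pass require_both_classes=False to allow"
                )

    out = []
    for s in slides:
        out.append(SlideRecord(s.slide_id, s.weak_label, s.patches, split=assignment[s.slide_id]))
    return out


def write_dataset(slides: Sequence[SlideRecord], outdir: str | Path) -> Path:
    """Write patches as PNG under per-slide directories plus a TSV manifest.

    Returns the manifest path.  Layout: ``<outdir>/<slide_id>/r{row}_c{col}.png``.
    """
    from PIL import Image

    from .tiling import write_manifest

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    materialized: list[SlideRecord] = []
    for s in slides:
        slide_dir = outdir / s.slide_id
        slide_dir.mkdir(exist_ok=True)
        patches = []
        for p in s.patches:
            if p.pixels is None:
                raise ValueError(f"patch ({s.slide_id}, {p.row}, {p.col}) has no pixel data to write")
            path = slide_dir / f"r{p.row}_c{p.col}.png"
            Image.fromarray(p.pixels).save(path)
            patches.append(
                PatchRecord(p.slide_id, p.row, p.col, pixels=None, path=str(path), instance_truth=p.instance_truth)
            )
        materialized.append(SlideRecord(s.slide_id, s.weak_label, patches, split=s.split))
    manifest = outdir / "manifest.tsv"
    write_manifest(materialized, manifest)
    return manifest
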