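"""Core record types shared across the pipeline.

A whole-slide image (WSI) is modelled as a *bag* of fixed-size patch
*instances*.  Only the bag carries a trusted label (the weak label); patch
labels exist only for synthetic data, where the generator knows which
patches carry the malignant motif.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: value used for PatchRecord.instance_truth when the patch label is unknown
#: (always the case for real slides).
UNKNOWN = None

VALID_SPLITS = ("train", "validation", "test")


@dataclass
class PatchRecord:
    """One instance: a fixed-size square patch cropped from a slide.

    ``instance_truth`` is 0/1 for synthetic patches and ``None`` (unknown)
    for real data.  ``pixels`` may be ``None`` when the patch lives on disk
    at ``path``.  ``aug`` tags the augmentation variant (``o`` original,
    ``h``/``v`` flips, ``j`` colour jitter).
    """

    slide_id: str
    row: int
    col: int
    pixels: Optional[np.ndarray] = None
    path: Optional[str] = None
    instance_truth: Optional[int] = UNKNOWN
    aug: str = "o"

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValueError(f"grid coordinates must be non-negative, got ({self.row}, {self.col})")
        if self.instance_truth not in (0, 1, UNKNOWN):
            raise ValueError(f"instance_truth must be 0, 1 or None, got {self.instance_truth!r}")

    def with_pixels(self, pixels: np.ndarray, aug: str = "o") -> "PatchRecord":
        return replace(self, pixels=pixels, aug=aug)


@dataclass
class SlideRecord:
    """One bag: a slide with its weak (slide-level) label and its patches."""

    slide_id: str
    weak_label: int
    patches: list[PatchRecord] = field(default_factory=list)
    split: Optional[str] = None

    def __post_init__(self) -> None:
        if self.weak_label not in (0, 1):
            raise ValueError(f"weak_label must be 0 (benign) or 1 (malignant), got {self.weak_label!r}")
        if self.split is not None and self.split not in VALID_SPLITS:
            raise ValueError(f"split must be one of {VALID_SPLITS}, got {self.split!r}")
        seen = set()
        for p in self.patches:
            key = (p.row, p.col)
            if key in seen:
                raise ValueError(f"slide {self.slide_id}: duplicate patch at grid position {key}")
            seen.add(key)

    @property
    def n_patches(self) -> int:
        return len(self.patches)


@dataclass
class PatchScore:
    """Predicted malignancy probability for one patch."""

    slide_id: str
    row: int
    col: int
    prob_malignant: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_malignant <= 1.0:
            raise ValueError(f"prob_malignant must lie in [0, 1], got {self.prob_malignant}")


def slides_by_id(slides: Sequence[SlideRecord]) -> dict[str, SlideRecord]:
    out: dict[str, SlideRecord] = {}
    for s in slides:
        if s.slide_id in out:
            raise ValueError(f"duplicate slide_id {s.slide_id!r}")
        out[s.slide_id] = s
    return out


def iter_patches(slides: Sequence[SlideRecord]):
    for s in slides:
        for p in s.patches:
            yield s, p
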