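"""Slide-level calls from patch probabilities, via two counting thresholds.

A patch is called malignant when its probability is *strictly* greater than
``patch_threshold`` (default 0.50); a slide is called malignant when it has
*strictly* more than ``slide_threshold`` malignant patches (default 10).
For ROC ranking the slide also gets a continuous score: by default the
fraction of malignant patches (the natural monotone extension of the
counting rule), optionally the mean of its top ``slide_threshold``
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .records import PatchScore, SlideRecord


@dataclass
class AggregationRule:
    patch_threshold: float = 0.50
    slide_threshold: int = 10
    score_mode: str = "fraction"  # {"fraction", "topk_mean"}

    def __post_init__(self) -> None:
        if not 0.0 <= self.patch_threshold <= 1.0:
            raise ValueError("patch_threshold must lie in [0, 1]")
        if self.slide_threshold < 0:
            raise ValueError("slide_threshold must be >= 0")
        if self.score_mode not in ("fraction", "topk_mean"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")


@dataclass
class SlidePrediction:
    slide_id: str
    n_patches: int
    n_malignant_patches: int
    predicted_label: int
    slide_score: float


def aggregate(scores: Sequence[PatchScore], rule: AggregationRule) -> list[SlidePrediction]:
    """One SlidePrediction per slide_id present in ``scores``.

    Slides are returned in first-appearance order.  A slide with zero
    patches cannot occur here by construction, but an empty score list
    raises.
    """
    if not scores:
        raise ValueError("no patch scores to aggregate")
    groups: dict[str, list[float]] = {}
    for sc in scores:
        groups.setdefault(sc.slide_id, []).append(sc.prob_malignant)
    preds = []
    for sid, probs in groups.items():
        n_mal = sum(p > rule.patch_threshold for p in probs)
        if rule.score_mode == "fraction":
            score = n_mal / len(probs)
        else:
            k = max(1, rule.slide_threshold)
            top = sorted(probs, reverse=True)[:k]
            score = sum(top) / len(top)
        preds.append(
            SlidePrediction(
                slide_id=sid,
                n_patches=len(probs),
                n_malignant_patches=n_mal,
                predicted_label=int(n_mal > rule.slide_threshold),
                slide_score=score,
            )
        )
    return preds


def predictions_frame(
    preds: Sequence[SlidePrediction], slides: Optional[Sequence[SlideRecord]] = None
) -> pd.DataFrame:
    """Predictions as a DataFrame; adds a ``true_label`` column when slides
    with weak labels are supplied."""
    df = pd.DataFrame(
        [
            {
                "slide_id": p.slide_id,
                "n_patches": p.n_patches,
                "n_malignant_patches": p.n_malignant_patches,
                "slide_score": p.slide_score,
                "predicted_label": p.predicted_label,
            }
            for p in preds
        ]
    )
    if slides is not None:
        truth = {s.slide_id: s.weak_label for s in slides}
        df["true_label"] = df["slide_id"].map(truth)
    return df
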