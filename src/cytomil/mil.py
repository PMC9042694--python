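"""Two-stage weakly supervised multiple-instance training with top-k selection.

The slide (bag) label is cast onto every patch (instance) it contains.
Stage 1 trains a patch scorer on *all* patches under these weak labels.
The stage-1 scorer then ranks the patches of each slide by predicted
malignancy probability; the top ``k_top`` patches of every slide enter a
second-stage training set with their slide's weak label, and each benign
slide additionally contributes ``n_neg_random`` random non-selected patches
(benign slides are clean by the MIL premise — every patch is truly
negative, so extra negatives are free).  Stage 2 fine-tunes the scorer on
this smaller, cleaner set.

The user-facing surface is the model/results pair :class:`TopKMIL` /
:class:`TopKMILResults`; the stage functions are importable directly for
composition and testing.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .nets import SmallCNN, bce_loss, preprocess
from .records import PatchRecord, PatchScore, SlideRecord, iter_patches, slides_by_id
from .seeding import child_seed, substream
from .tiling import load_patch_pixels

PROVENANCES = ("topk_pos", "topk_neg", "random_neg")


@dataclass
class MILConfig:
    """Hyperparameters of the two-stage MIL trainer.

    ``k_top`` instances per slide are kept after ranking (the classic MIL
    limit is ``k_top=1``); ``n_neg_random`` extra random patches per benign
    slide balance the second-stage classes.  The optimizer is SGD with
    momentum on binary cross-entropy; none of these were prescribed by the
    problem, so they are all exposed here.
    """

    k_top: int = 10
    n_neg_random: int = 10
    epochs_stage1: int = 2
    epochs_stage2: int = 8
    learning_rate: float = 0.02
    momentum: float = 0.9
    batch_size: int = 32
    seed: int = 0
    init: str = "random"  # {"random", "imagenet_pretrained"}
    backbone: str = "small_cnn"  # {"small_cnn"}
    input_px: int = 32
    iterate_rounds: int = 1

    def __post_init__(self) -> None:
        if self.k_top < 1:
            raise ValueError("k_top must be >= 1")
        if self.n_neg_random < 0:
            raise ValueError("n_neg_random must be >= 0")
        if self.init not in ("random", "imagenet_pretrained"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.iterate_rounds < 1:
            raise ValueError("iterate_rounds must be >= 1")


class PatchClassifier:
    """Trainable patch scorer: image -> malignancy probability in [0, 1].

    Wraps a backbone network (currently ``small_cnn``) together with the
    input size it expects.  Scoring is deterministic given fixed weights.
    """

    def __init__(self, backbone_name: str = "small_cnn", input_px: int = 32, seed: int = 0):
        if backbone_name != "small_cnn":
            raise ValueError(
                f"backbone {backbone_name!r} is not available in this build; "
                "only 'small_cnn' is provided"
            )
        self.backbone_name = backbone_name
        self.input_px = int(input_px)
        self.net = SmallCNN(input_px=input_px, seed=seed)

    def predict_proba(self, images: Sequence[np.ndarray], batch_size: int = 64) -> np.ndarray:
        """Malignancy probability for each image, batched."""
        probs = []
        for start in range(0, len(images), batch_size):
            x = preprocess(images[start : start + batch_size], self.input_px)
            probs.append(self.net.forward(x))
        return np.concatenate(probs) if probs else np.empty(0)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path, config: Optional[MILConfig] = None) -> None:
        """Single-file checkpoint with the (optional) run config embedded."""
        meta = {"backbone_name": self.backbone_name, "input_px": self.input_px}
        if config is not None:
            meta["config"] = asdict(config)
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **self.net.params)

    @classmethod
    def load(cls, path: str | Path) -> "PatchClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        clf = cls(meta["backbone_name"], input_px=meta["input_px"])
        clf.net.load_state_dict(state)
        return clf


@dataclass
class ManifestEntry:
    patch: PatchRecord
    assigned_label: int
    provenance: str
    prob_at_selection: float

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.assigned_label not in (0, 1):
            raise ValueError("assigned_label must be 0 or 1")


@dataclass
class TrainingManifest:
    """The stage-2 training set assembled by top-k selection and negative sampling."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_positive(self) -> int:
        return sum(e.assigned_label == 1 for e in self.entries)

    @property
    def n_negative(self) -> int:
        return sum(e.assigned_label == 0 for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "slide_id": e.patch.slide_id,
                    "row": e.patch.row,
                    "col": e.patch.col,
                    "assigned_label": e.assigned_label,
                    "provenance": e.provenance,
                    "prob_at_selection": e.prob_at_selection,
                }
                for e in self.entries
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def score_all_patches(
    model: PatchClassifier, slides: Sequence[SlideRecord], batch_size: int = 64
) -> list[PatchScore]:
    """Score every patch of every slide (one PatchScore per patch, in order)."""
    if not slides:
        raise ValueError("no slides to score")
    keys, images = [], []
    for s, p in iter_patches(slides):
        keys.append((s.slide_id, p.row, p.col))
        images.append(load_patch_pixels(p))
    probs = model.predict_proba(images, batch_size=batch_size)
    return [PatchScore(sid, r, c, float(pr)) for (sid, r, c), pr in zip(keys, probs)]


def select_topk(
    scores: Sequence[PatchScore], slides: Sequence[SlideRecord], cfg: MILConfig
) -> TrainingManifest:
    """Build the stage-2 manifest: per-slide top-k plus random benign extras.

    Per slide, the ``min(k_top, n_patches)`` highest-probability patches are
    taken with the slide's weak label (ties broken by (row, col) order);
    each benign slide then contributes ``min(n_neg_random, n_remaining)``
    uniformly random non-selected patches as additional negatives.  The
    random draw is seeded from the config's ``seed``.
    """
    by_id = slides_by_id(slides)
    score_map: dict[str, list[PatchScore]] = {}
    for sc in scores:
        if sc.slide_id not in by_id:
            raise ValueError(f"score refers to unknown slide {sc.slide_id!r}")
        score_map.setdefault(sc.slide_id, []).append(sc)

    rng = substream(cfg.seed, "negatives")
    entries: list[ManifestEntry] = []
    for s in slides:
        slide_scores = score_map.get(s.slide_id, [])
        patch_map = {(p.row, p.col): p for p in s.patches}
        if {(sc.row, sc.col) for sc in slide_scores} != set(patch_map):
            raise ValueError(f"scores do not cover all patches of slide {s.slide_id!r}")
        ranked = sorted(slide_scores, key=lambda sc: (-sc.prob_malignant, sc.row, sc.col))
        k = min(cfg.k_top, len(ranked))
        provenance = "topk_pos" if s.weak_label == 1 else "topk_neg"
        for sc in ranked[:k]:
            entries.append(ManifestEntry(patch_map[(sc.row, sc.col)], s.weak_label, provenance, sc.prob_malignant))
        if s.weak_label == 0 and cfg.n_neg_random > 0:
            remaining = ranked[k:]
            n_draw = min(cfg.n_neg_random, len(remaining))
            if n_draw:
                chosen = rng.choice(len(remaining), size=n_draw, replace=False)
                for j in sorted(chosen.tolist()):
                    sc = remaining[j]
                    entries.append(ManifestEntry(patch_map[(sc.row, sc.col)], 0, "random_neg", sc.prob_malignant))
    return TrainingManifest(entries)


def _train_loop(
    model: PatchClassifier,
    images: list[np.ndarray],
    labels: np.ndarray,
    epochs: int,
    cfg: MILConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Shuffled mini-batch SGD; returns per-epoch loss history."""
    x_all = preprocess(images, model.input_px)
    history = []
    n = len(labels)
    for epoch in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = model.net.loss_and_grads(x_all[idx], labels[idx])
            model.net.sgd_step(grads, lr=cfg.learning_rate, momentum=cfg.momentum)
        probs = model.net.forward(x_all)
        history.append(
            {
                "epoch": epoch,
                "loss": bce_loss(probs, labels),
                "accuracy": float(((probs > 0.5).astype(int) == labels).mean()),
            }
        )
    return history


def train_stage(
    model: PatchClassifier, manifest: TrainingManifest, cfg: MILConfig, stage: int = 2
) -> tuple[PatchClassifier, list[dict]]:
    """Update the classifier on a training manifest (fine-tunes in place).

    Returns the model and a per-epoch history of loss/accuracy on the
    manifest.  ``learning_rate=0`` leaves the weights bit-identical.
    """
    if len(manifest) == 0:
        raise ValueError("training manifest is empty")
    images = [load_patch_pixels(e.patch) for e in manifest.entries]
    labels = np.array([e.assigned_label for e in manifest.entries], dtype=np.float64)
    epochs = cfg.epochs_stage1 if stage == 1 else cfg.epochs_stage2
    rng = substream(cfg.seed, f"training_stage{stage}")
    history = _train_loop(model, images, labels, epochs, cfg, rng)
    return model, history


def build_classifier(cfg: MILConfig) -> PatchClassifier:
    if cfg.init == "imagenet_pretrained":
        raise ValueError(
            "imagenet_pretrained initialisation requires an external weights file, "
            "which this build does not bundle; use init='random'"
        )
    return PatchClassifier(cfg.backbone, input_px=cfg.input_px, seed=child_seed(cfg.seed, "weights"))


def fit_mil(slides: Sequence[SlideRecord], cfg: MILConfig) -> tuple[PatchClassifier, dict]:
    """Run the full two-stage procedure; returns (model, run log).

    Stage 1 trains on every patch under its slide's weak label; the stage-1
    model scores all patches; :func:`select_topk` assembles the stage-2
    manifest; stage 2 fine-tunes on it.  With ``iterate_rounds > 1`` the
    rank/select/update cycle is repeated.
    """
    labels = {s.weak_label for s in slides}
    if labels != {0, 1}:
        raise ValueError("training slides must contain both classes")
    model = build_classifier(cfg)
    log: dict = {"config": asdict(cfg), "stages": []}

    t0 = time.perf_counter()
    weak_manifest = TrainingManifest(
        [
            ManifestEntry(p, s.weak_label, "topk_pos" if s.weak_label else "topk_neg", 0.5)
            for s, p in iter_patches(slides)
        ]
    )
    _, hist1 = train_stage(model, weak_manifest, cfg, stage=1)
    log["stages"].append(
        {"stage": 1, "n_patches": len(weak_manifest), "history": hist1, "seconds": time.perf_counter() - t0}
    )

    manifest = None
    for round_idx in range(cfg.iterate_rounds):
        t1 = time.perf_counter()
        scores = score_all_patches(model, slides)
        manifest = select_topk(scores, slides, cfg)
        _, hist2 = train_stage(model, manifest, cfg, stage=2)
        log["stages"].append(
            {
                "stage": 2,
                "round": round_idx,
                "n_manifest": len(manifest),
                "n_positive": manifest.n_positive,
                "n_negative": manifest.n_negative,
                "history": hist2,
                "seconds": time.perf_counter() - t1,
            }
        )
    log["manifest"] = manifest
    return model, log


# ---------------------------------------------------------------------------
# model / results surface
# ---------------------------------------------------------------------------


class TopKMIL:
    """Weakly supervised top-k MIL slide classifier (model object).

    Built from a list of :class:`SlideRecord` bags carrying slide-level
    labels only; :meth:`fit` runs the two-stage procedure and returns a
    :class:`TopKMILResults`.
    """

    def __init__(self, slides: Sequence[SlideRecord], config: Optional[MILConfig] = None):
        self.slides = list(slides)
        self.config = config if config is not None else MILConfig()

    @classmethod
    def from_manifest(cls, manifest_path: str | Path, config: Optional[MILConfig] = None, split: str = "train"):
        """Build from a dataset manifest TSV, keeping slides of ``split``."""
        from .tiling import read_manifest

        slides = [s for s in read_manifest(manifest_path) if split is None or s.split == split]
        return cls(slides, config)

    def fit(self) -> "TopKMILResults":
        model, log = fit_mil(self.slides, self.config)
        return TopKMILResults(self, model, log)


class TopKMILResults:
    """Fit results: the trained scorer, the stage log, and prediction helpers."""

    def __init__(self, model: TopKMIL, classifier: PatchClassifier, log: dict):
        self.model = model
        self.classifier = classifier
        self.log = log
        self.manifest: TrainingManifest = log.pop("manifest")

    def score_patches(self, slides: Sequence[SlideRecord]) -> list[PatchScore]:
        return score_all_patches(self.classifier, slides)

    def predict(self, slides: Sequence[SlideRecord], rule=None) -> pd.DataFrame:
        """Slide-level predictions for ``slides`` under an aggregation rule."""
        from .aggregation import AggregationRule, aggregate, predictions_frame

        rule = rule if rule is not None else AggregationRule()
        preds = aggregate(self.score_patches(slides), rule)
        return predictions_frame(preds, slides)

    def save(self, path: str | Path) -> None:
        self.classifier.save(path, config=self.model.config)

    def summary(self) -> str:
        cfg = self.model.config
        n_mal = sum(s.weak_label == 1 for s in self.model.slides)
        n_ben = len(self.model.slides) - n_mal
        lines = [
            "Top-k multiple-instance slide classifier",
            "=" * 44,
            f"training slides        {len(self.model.slides)} ({n_mal} malignant / {n_ben} benign)",
            f"backbone               {self.classifier.backbone_name} (input {self.classifier.input_px} px)",
            f"k_top / n_neg_random   {cfg.k_top} / {cfg.n_neg_random}",
            f"stage-2 manifest       {len(self.manifest)} patches "
            f"({self.manifest.n_positive} pos / {self.manifest.n_negative} neg)",
        ]
        for st in self.log["stages"]:
            hist = st["history"]
            lines.append(
                f"stage {st['stage']}                {len(hist)} epochs, "
                f"final loss {hist[-1]['loss']:.4f}, train acc {hist[-1]['accuracy']:.3f} "
                f"({st['seconds']:.1f}s)"
            )
        return "\n".join(lines)
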