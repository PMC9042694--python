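"""Two-stage MIL trainer: scoring, top-k selection, stage training."""

import dataclasses

import numpy as np
import pytest

from cytomil.mil import (
    ManifestEntry,
    MILConfig,
    PatchClassifier,
    TrainingManifest,
    fit_mil,
    score_all_patches,
    select_topk,
    train_stage,
)
from cytomil.records import PatchRecord, PatchScore, SlideRecord


def _grid_slide(slide_id, label, n, probs=None):
    """A slide of n patches laid out on one row; optional fixed scores."""
    patches = [PatchRecord(slide_id, 0, c) for c in range(n)]
    slide = SlideRecord(slide_id, label, patches)
    scores = None
    if probs is not None:
        scores = [PatchScore(slide_id, 0, c, p) for c, p in enumerate(probs)]
    return slide, scores


# --- scoring ----------------------------------------------------------------


def test_score_all_patches_count_and_determinism(tiny_slides):
    clf = PatchClassifier(input_px=32, seed=0)
    scores = score_all_patches(clf, tiny_slides)
    assert len(scores) == sum(s.n_patches for s in tiny_slides)
    again = score_all_patches(clf, tiny_slides)
    assert [s.prob_malignant for s in scores] == [s.prob_malignant for s in again]
    assert all(0.0 <= s.prob_malignant <= 1.0 for s in scores)


def test_constant_head_scores_all_patches_equally(tiny_slides):
    """Zeroing the linear head makes every patch score sigmoid(0) = 0.5."""
    clf = PatchClassifier(input_px=32, seed=0)
    clf.net.params["fc_W"][:] = 0.0
    clf.net.params["fc_b"][:] = 0.0
    scores = score_all_patches(clf, tiny_slides)
    assert {s.prob_malignant for s in scores} == {0.5}


# --- top-k selection --------------------------------------------------------


def test_select_topk_matches_full_sort_oracle():
    """Selected probabilities dominate all non-selected ones; the selected
    set equals the full-sort-and-slice oracle (ties broken by (row, col))."""
    rng = np.random.default_rng(0)
    for trial in range(200):
        n = int(rng.integers(1, 30))
        k = int(rng.integers(1, 15))
        probs = rng.integers(0, 8, size=n) / 7.0  # coarse grid forces ties
        label = int(rng.integers(0, 2))
        slide, scores = _grid_slide("s", label, n, probs)
        cfg = MILConfig(k_top=k, n_neg_random=0, seed=1)
        manifest = select_topk(scores, [slide], cfg)
        oracle = sorted(zip(probs, range(n)), key=lambda t: (-t[0], t[1]))[: min(k, n)]
        assert [(e.patch.col, e.prob_at_selection) for e in manifest.entries] == [
            (c, p) for p, c in oracle
        ]
        if len(manifest) < n:
            worst_kept = min(e.prob_at_selection for e in manifest.entries)
            dropped = set(range(n)) - {e.patch.col for e in manifest.entries}
            assert all(probs[c] <= worst_kept for c in dropped)


def test_select_topk_truncates_small_slides():
    slide, scores = _grid_slide("s", 1, 6, [0.1, 0.9, 0.5, 0.3, 0.8, 0.2])
    manifest = select_topk(scores, [slide], MILConfig(k_top=10, n_neg_random=0))
    assert len(manifest) == 6


def test_select_topk_one_malignant_one_benign_slide():
    """16+16 patches, k=10, 10 random negatives: 10 positive entries and
    10 + 6 = 16 benign entries (only 6 non-selected patches remain)."""
    rng = np.random.default_rng(2)
    mal, mal_scores = _grid_slide("m", 1, 16, rng.uniform(size=16))
    ben, ben_scores = _grid_slide("b", 0, 16, rng.uniform(size=16))
    cfg = MILConfig(k_top=10, n_neg_random=10, seed=3)
    manifest = select_topk(mal_scores + ben_scores, [mal, ben], cfg)
    assert manifest.n_positive == 10
    assert manifest.n_negative == 16
    by_prov = {prov: [e for e in manifest.entries if e.provenance == prov] for prov in
               ("topk_pos", "topk_neg", "random_neg")}
    assert [len(by_prov[p]) for p in ("topk_pos", "topk_neg", "random_neg")] == [10, 10, 6]
    # invariants: topk label equals the slide's weak label; randoms are benign
    assert all(e.assigned_label == 1 and e.patch.slide_id == "m" for e in by_prov["topk_pos"])
    assert all(e.assigned_label == 0 and e.patch.slide_id == "b" for e in by_prov["topk_neg"] + by_prov["random_neg"])
    # random negatives never duplicate top-k selections
    sel = {(e.patch.slide_id, e.patch.row, e.patch.col) for e in manifest.entries}
    assert len(sel) == len(manifest)


def test_select_topk_k1_is_classic_mil():
    slides, scores = [], []
    rng = np.random.default_rng(4)
    for i, label in enumerate([1, 1, 0]):
        s, sc = _grid_slide(f"s{i}", label, 8, rng.uniform(size=8))
        slides.append(s)
        scores += sc
    manifest = select_topk(scores, slides, MILConfig(k_top=1, n_neg_random=2, seed=0))
    assert sum(e.provenance.startswith("topk") for e in manifest.entries) == 3
    assert sum(e.provenance == "random_neg" for e in manifest.entries) == 2


def test_select_topk_unknown_slide_raises():
    slide, scores = _grid_slide("s", 1, 4, [0.1, 0.2, 0.3, 0.4])
    scores.append(PatchScore("ghost", 0, 0, 0.5))
    with pytest.raises(ValueError, match="unknown slide"):
        select_topk(scores, [slide], MILConfig())


def test_select_topk_incomplete_coverage_raises():
    slide, scores = _grid_slide("s", 1, 4, [0.1, 0.2, 0.3, 0.4])
    with pytest.raises(ValueError, match="cover all patches"):
        select_topk(scores[:-1], [slide], MILConfig())


# --- stage training ---------------------------------------------------------


def _manifest_from(slides, label_by_truth=True, max_neg=None):
    entries = []
    n_neg = 0
    for s in slides:
        for p in s.patches:
            lab = p.instance_truth if label_by_truth else s.weak_label
            if lab == 0:
                n_neg += 1
                if max_neg is not None and n_neg > max_neg:
                    continue
            entries.append(ManifestEntry(p, lab, "topk_pos" if lab else "topk_neg", 0.5))
    return TrainingManifest(entries)


def test_zero_learning_rate_leaves_weights_untouched(tiny_slides, fast_mil_cfg):
    cfg = dataclasses.replace(fast_mil_cfg, learning_rate=0.0)
    clf = PatchClassifier(input_px=32, seed=1)
    before = clf.net.state_dict()
    train_stage(clf, _manifest_from(tiny_slides), cfg, stage=2)
    for k, v in clf.net.state_dict().items():
        np.testing.assert_array_equal(v, before[k])


def test_loss_decreases_and_separable_manifest_is_learned(tiny_slides, fast_mil_cfg):
    """Instance-true labels are separable by construction: accuracy >= 0.95."""
    cfg = dataclasses.replace(fast_mil_cfg, epochs_stage2=15, learning_rate=0.05)
    clf = PatchClassifier(input_px=32, seed=1)
    manifest = _manifest_from(tiny_slides, max_neg=24)
    _, hist = train_stage(clf, manifest, cfg, stage=2)
    assert hist[-1]["loss"] < hist[0]["loss"]
    assert hist[-1]["accuracy"] >= 0.95


def test_single_batch_overfit(tiny_slides):
    """8 patches, 200 SGD steps: the scorer memorises the manifest."""
    pos = [p for s in tiny_slides for p in s.patches if p.instance_truth == 1][:4]
    neg = [p for s in tiny_slides for p in s.patches if p.instance_truth == 0][:4]
    manifest = TrainingManifest(
        [ManifestEntry(p, 1, "topk_pos", 0.5) for p in pos]
        + [ManifestEntry(p, 0, "topk_neg", 0.5) for p in neg]
    )
    cfg = MILConfig(epochs_stage2=200, batch_size=8, learning_rate=0.05, seed=2, input_px=32)
    clf = PatchClassifier(input_px=32, seed=2)
    _, hist = train_stage(clf, manifest, cfg, stage=2)
    assert hist[-1]["accuracy"] == 1.0


def test_empty_manifest_raises(fast_mil_cfg):
    with pytest.raises(ValueError, match="empty"):
        train_stage(PatchClassifier(input_px=32), TrainingManifest([]), fast_mil_cfg)


# --- full fit ---------------------------------------------------------------


def test_fit_mil_requires_both_classes(tiny_slides, fast_mil_cfg):
    benign_only = [s for s in tiny_slides if s.weak_label == 0]
    with pytest.raises(ValueError, match="both classes"):
        fit_mil(benign_only, fast_mil_cfg)


def test_fit_mil_runs_both_stages_and_builds_manifest(tiny_slides, fast_mil_cfg):
    model, log = fit_mil(tiny_slides, fast_mil_cfg)
    stages = [st["stage"] for st in log["stages"]]
    assert stages == [1, 2]
    manifest = log["manifest"]
    # per slide: k_top entries, plus up to n_neg_random randoms per benign slide
    assert len(manifest) == 6 * fast_mil_cfg.k_top + 3 * fast_mil_cfg.n_neg_random
    for e in manifest.entries:
        if e.provenance.startswith("topk"):
            weak = next(s.weak_label for s in tiny_slides if s.slide_id == e.patch.slide_id)
            assert e.assigned_label == weak


def test_resnet18_backbone_unavailable():
    with pytest.raises(ValueError, match="small_cnn"):
        PatchClassifier("resnet18")


def test_checkpoint_round_trip(tmp_path, tiny_slides):
    clf = PatchClassifier(input_px=32, seed=3)
    path = tmp_path / "model.npz"
    clf.save(path, config=MILConfig(seed=3))
    back = PatchClassifier.load(path)
    imgs = [tiny_slides[0].patches[i].pixels for i in range(4)]
    np.testing.assert_allclose(clf.predict_proba(imgs), back.predict_proba(imgs))
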