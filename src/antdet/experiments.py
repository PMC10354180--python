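"""Benchmark experiments on synthetic clips.

These functions pin down the study conditions used to exercise the full
framework at desk scale and are shared by the test suite, the acceptance
script and the worked example in the README. Each takes a single integer
seed that drives clip generation and every stochastic training component.

Conditions (see docs/methods.md for rationale): 20 training clips and 6
held-out clips of 24 frames at 64x64, 3 ants, 1 disk distractor and
wind jitter enabled (the two noise regimes); detectors are depth-2
U-Net-style models with 8 base channels trained for 600 iterations
(learning-rate switch at 450) on batches of four 32x32 crops.
"""

from __future__ import annotations

import numpy as np

from .estimators import (HybridDetector, ProbabilisticNNFitDistiller,
                         PseudoLabelDetector)
from .evaluation import evaluate_video, labelmap_to_centers
from .foreground import annotate_sequence, extract_foreground_fe1
from .foreground import extract_foreground_median
from .synthetic import SynthConfig, generate_video, rasterize_gt_labelmap
from .training import render_human_annotation

__all__ = [
    "make_clips",
    "fe1_annotations",
    "median_annotations",
    "labelmaps_to_scores",
    "pseudo_label_experiment",
    "ensemble_experiment",
    "hybrid_experiment",
]

# desk-scale study conditions
N_TRAIN_CLIPS = 20
N_TEST_CLIPS = 6
FE_PARAMS = dict(min_area=5, boundary_radius=2)
EVAL_PARAMS = dict(min_area=5, connectivity=8)
DIST_THRESHOLD = 5.0
# foreground classes cover only a few percent of pixels; without class
# weighting the cross-entropy sporadically converges to the all-background
# solution at this capacity, so all benchmark detectors weight the body
# and boundary classes 5x
DETECTOR_PARAMS = dict(architecture="unet", depth=2, base_channels=8,
                       batch_size=4, crop_size=32, total_iters=600,
                       lr_switch_iter=450, class_weights=(1.0, 5.0, 5.0))
# the two-headed variant needs a wider full-resolution feature map to feed
# two independently initialized heads; every model in the hybrid
# comparison shares this capacity so the comparison is architecture-fair
HYBRID_DETECTOR_PARAMS = dict(DETECTOR_PARAMS, base_channels=16)

# per-clip scene variability, emulating footage captured across different
# nights and camera placements: each clip draws its own background
# brightness, texture strength, ant contrast and colony activity
CLIP_VARIABILITY = dict(background_level=(0.40, 0.70),
                        background_texture_sigma=(0.05, 0.12),
                        ant_contrast=(0.25, 0.45),
                        n_ants=(2, 4))


def make_clips(n_clips: int, seed: int, **overrides):
    """Generate ``n_clips`` heterogeneous videos.

    Scene parameters vary per clip (ranges in ``CLIP_VARIABILITY``) from a
    stream derived from ``seed``; explicit ``overrides`` take precedence.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20230718]))
    clips = []
    for i in range(n_clips):
        lo, hi = CLIP_VARIABILITY["background_level"]
        params = {"background_level": float(rng.uniform(lo, hi))}
        lo, hi = CLIP_VARIABILITY["background_texture_sigma"]
        params["background_texture_sigma"] = float(rng.uniform(lo, hi))
        lo, hi = CLIP_VARIABILITY["ant_contrast"]
        params["ant_intensity_offset"] = -float(rng.uniform(lo, hi))
        lo, hi = CLIP_VARIABILITY["n_ants"]
        params["n_ants"] = int(rng.integers(lo, hi + 1))
        params["seed"] = seed + i
        params.update(overrides)
        clips.append(generate_video(SynthConfig(**params)))
    return clips


def _concat(videos):
    frames = np.concatenate([v.frames for v in videos])
    gt = [c for v in videos for c in v.gt_centers]
    return frames, gt


def fe1_annotations(videos, T=2.5):
    """FE-1 pseudo-annotations, computed per clip (statistics are temporal
    and must not mix clips), concatenated over clips."""
    return np.concatenate([
        annotate_sequence(extract_foreground_fe1(v.frames, T=T), **FE_PARAMS)
        for v in videos])


def median_annotations(videos, k_mad=3.0):
    """Median/MAD pseudo-annotations per clip, concatenated."""
    return np.concatenate([
        annotate_sequence(extract_foreground_median(v.frames, k_mad=k_mad),
                          **FE_PARAMS)
        for v in videos])


def labelmaps_to_scores(labelmaps, gt_centers):
    """Micro-averaged detection P/R/F1 of dense label maps vs gt centers."""
    pred = [labelmap_to_centers(lm, **EVAL_PARAMS) for lm in labelmaps]
    return evaluate_video(gt_centers, pred, dist_threshold=DIST_THRESHOLD)


def _score_detector(det, test_videos):
    frames, gt = _concat(test_videos)
    return labelmaps_to_scores(det.predict(frames), gt)


def pseudo_label_experiment(seed: int, total_iters: int | None = None) -> dict:
    """Noisy-label cleanup: a detector trained on FE-1 pseudo-annotations
    vs FE-1 itself, both scored on held-out clips.

    The trained network should keep FE-1's true positives (recall close to
    FE-1's) while suppressing its inconsistent false positives (precision
    above FE-1's).
    """
    train_videos = make_clips(N_TRAIN_CLIPS, seed)
    test_videos = make_clips(N_TEST_CLIPS, seed + 1000)
    train_frames, _ = _concat(train_videos)
    aa = fe1_annotations(train_videos)

    params = dict(DETECTOR_PARAMS)
    if total_iters is not None:
        params["total_iters"] = total_iters
        params["lr_switch_iter"] = int(0.75 * total_iters)
    det = PseudoLabelDetector(**params, random_state=seed).fit(train_frames, aa)

    _, test_gt = _concat(test_videos)
    fe1_test = fe1_annotations(test_videos)
    fe1_scores = labelmaps_to_scores(fe1_test, test_gt)
    student_scores = _score_detector(det, test_videos)
    return {
        "fe1_precision": fe1_scores.precision,
        "fe1_recall": fe1_scores.recall,
        "fe1_f1": fe1_scores.f1,
        "student_precision": student_scores.precision,
        "student_recall": student_scores.recall,
        "student_f1": student_scores.f1,
    }


def ensemble_experiment(seed: int) -> dict:
    """Probabilistic NN-Fit distillation from two diversely supervised
    teachers (FE-1-trained and median-extractor-trained)."""
    from .training import make_network_sources

    train_videos = make_clips(N_TRAIN_CLIPS, seed)
    test_videos = make_clips(N_TEST_CLIPS, seed + 1000)
    train_frames, _ = _concat(train_videos)

    teachers = []
    scores = {}
    for name, ann in (("fe1", fe1_annotations(train_videos)),
                      ("median", median_annotations(train_videos))):
        det = PseudoLabelDetector(**DETECTOR_PARAMS,
                                  random_state=seed).fit(train_frames, ann)
        teachers.append(det.model_)
        scores[f"teacher_{name}_f1"] = _score_detector(det, test_videos).f1

    sources = make_network_sources(train_frames, teachers,
                                   names=["fe1_net", "median_net"])
    # students distilled from hard teacher maps converge more slowly than
    # teachers trained on FE labels; give the student twice the iterations
    student_params = dict(DETECTOR_PARAMS, total_iters=1200,
                          lr_switch_iter=900)
    student = ProbabilisticNNFitDistiller(
        **student_params, random_state=seed + 1,
        temperature=0.1, warmup_iters=150).fit(train_frames, sources)
    scores["student_f1"] = _score_detector(student, test_videos).f1
    scores["best_teacher_f1"] = max(scores["teacher_fe1_f1"],
                                    scores["teacher_median_f1"])
    return scores


def hybrid_experiment(seed: int, ha_clip_fraction: float = 0.1) -> dict:
    """Joint algorithm + human annotation training.

    Human point annotations (rendered as clean disks from the ground-truth
    centers) cover the first 10% of the training clips; FE-1 annotations
    cover the rest. Compares: human-only training, the two-headed hybrid,
    and the single-output variant that simply mixes both label styles.
    """
    train_videos = make_clips(N_TRAIN_CLIPS, seed)
    test_videos = make_clips(N_TEST_CLIPS, seed + 1000)
    n_ha_clips = max(1, int(round(ha_clip_fraction * len(train_videos))))
    frames_per_clip = train_videos[0].frames.shape[0]
    n_ha_frames = n_ha_clips * frames_per_clip

    train_frames, train_gt = _concat(train_videos)
    H, W = train_frames.shape[1:]
    aa = fe1_annotations(train_videos)
    ha = render_human_annotation(train_gt, (H, W), disk_radius=3,
                                 boundary_radius=2)
    ha_idx = np.arange(n_ha_frames)
    aa_idx = np.arange(n_ha_frames, train_frames.shape[0])

    ha_only = PseudoLabelDetector(**HYBRID_DETECTOR_PARAMS,
                                  random_state=seed).fit(
        train_frames[ha_idx], ha[ha_idx])

    hybrid = HybridDetector(**HYBRID_DETECTOR_PARAMS, random_state=seed).fit(
        train_frames, algorithm_labels=aa, human_labels=ha,
        algorithm_indices=aa_idx, human_indices=ha_idx)

    mixed = aa.copy()
    mixed[ha_idx] = ha[ha_idx]
    single_mixed = PseudoLabelDetector(**HYBRID_DETECTOR_PARAMS,
                                       random_state=seed).fit(
        train_frames, mixed)

    return {
        "ha_only_f1": _score_detector(ha_only, test_videos).f1,
        "hybrid_f1": _score_detector(hybrid, test_videos).f1,
        "single_mixed_f1": _score_detector(single_mixed, test_videos).f1,
        "n_human_frames": int(n_ha_frames),
        "n_algorithm_frames": int(len(aa_idx)),
    }
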