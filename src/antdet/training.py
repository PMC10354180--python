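"""Learning procedures for dense ant detectors.

Four trainers share one stochastic-gradient engine (Adam, two-phase
learning-rate schedule, random square crops):

* :func:`train_single_source` — ordinary training on one annotation
  source, minimizing the mean spatial cross-entropy
  ``(1/N) * sum_i L(tau_theta(x_i), y_i)``.
* :func:`train_probabilistic_nn_fit` — ensemble distillation from K >= 1
  annotation versions. Per iteration and per image sample, each version k
  gets a selection probability ``p_k = softmax(-d_k / temperature)``
  where ``d_k`` is the distance between the student's current prediction
  and version k's labels (mean per-pixel cross-entropy by default, L1 on
  probability maps optionally); one version is then sampled per image for
  the gradient step. During an initial warm-up phase the selection is
  uniform. Low-distance (easy-to-fit) versions are favoured, which breaks
  consistent labeling mistakes that no single source escapes.
* :func:`train_random_nn_fit` — the two-stage baseline: uniformly random
  selection before ``switch_iter``, greedy minimum-distance selection
  after. It is the ``temperature -> 0`` limit of the probabilistic rule.
* :func:`train_hybrid` — two-headed training on algorithm annotations
  (head 1) and human annotations (head 2). Each batch mixes samples from
  both pools; a sample's loss flows only through its own head while the
  shared trunk receives gradients from both.

Batch sampling and source selection consume *separate* seeded random
streams, so with K = 1 every ensemble trainer takes exactly the same
label sequence as single-source training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.morphology import dilation as _dilation, disk as _disk_footprint

from ._nn import Adam, cross_entropy_loss_grad, softmax
from .models import DetectorModel, predict_labelmap, predict_proba

__all__ = [
    "TrainConfig",
    "EnsembleConfig",
    "AnnotationSource",
    "train_single_source",
    "train_probabilistic_nn_fit",
    "train_random_nn_fit",
    "train_hybrid",
    "make_network_sources",
    "average_ensemble_predict",
    "render_human_annotation",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    The two-phase Adam schedule (high initial rate, 10x lower after the
    switch iteration) follows standard practice for this task family; the
    full-scale settings are batch 8, lr 5e-4 -> 5e-5 switching at 30000
    iterations. Defaults here keep the schedule shape at desk scale.
    """

    batch_size: int = 8
    lr_initial: float = 5e-4
    lr_after: float = 5e-5
    lr_switch_iter: int = 1500
    total_iters: int = 2000
    crop_size: int = 32
    seed: int = 0
    class_weights: Sequence[float] | None = None

    def __post_init__(self):
        if self.lr_initial <= 0 or self.lr_after <= 0:
            raise ValueError("learning rates must be > 0")
        if self.lr_switch_iter > self.total_iters:
            raise ValueError("lr_switch_iter must be <= total_iters")


@dataclass(frozen=True)
class EnsembleConfig:
    """Probabilistic NN-Fit settings.

    ``temperature`` controls the sharpness of the selection softmax
    (smaller = greedier; the 0 limit recovers greedy NN-Fit).
    ``warmup_iters`` iterations of uniform selection mirror the random-fit
    stage the probabilistic rule generalizes.
    """

    temperature: float = 0.1
    distance: str = "pixel_ce"
    warmup_iters: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.warmup_iters < 0:
            raise ValueError("warmup_iters must be >= 0")
        if self.distance not in ("pixel_ce", "l1_prob"):
            raise ValueError("distance must be 'pixel_ce' or 'l1_prob'")


@dataclass
class AnnotationSource:
    """One annotation version: a dense label map per training frame."""

    name: str
    labelmaps: np.ndarray          # (N, H, W) integer classes
    origin: str = "algorithm"      # algorithm | human | network

    def __post_init__(self):
        self.labelmaps = np.asarray(self.labelmaps)
        if self.origin not in ("algorithm", "human", "network"):
            raise ValueError(f"unknown origin {self.origin!r}")


def _check_labels(labelmaps, n_classes=3):
    lm = np.asarray(labelmaps)
    if lm.min() < 0 or lm.max() >= n_classes:
        raise ValueError(
            f"label values must lie in [0, {n_classes}); "
            f"got range [{lm.min()}, {lm.max()}]")
    return lm.astype(np.int64)


def _as_frames(frames):
    frames = np.asarray(frames, dtype=np.float32)
    if frames.ndim != 3:
        raise ValueError("frames must be (N, H, W) grayscale")
    return frames


class _SGDEngine:
    """Shared batch sampler + Adam stepper with the two-phase schedule."""

    def __init__(self, frames, model: DetectorModel, cfg: TrainConfig):
        self.frames = _as_frames(frames)
        self.model = model
        self.cfg = cfg
        self.rng_batch = np.random.default_rng(
            np.random.SeedSequence(cfg.seed))
        self.adam = Adam(model.parameters(), lr=cfg.lr_initial)
        N, H, W = self.frames.shape
        self.crop = min(cfg.crop_size, H, W)
        mult = 2 ** model.depth
        self.crop -= self.crop % mult
        if self.crop < mult:
            raise ValueError("crop_size too small for the model depth")
        self.loss_history: list[float] = []

    def sample_batch(self, n_frames=None):
        """Random (frame, crop-origin) triples for one batch."""
        N, H, W = self.frames.shape
        n_frames = N if n_frames is None else n_frames
        b = self.cfg.batch_size
        idx = self.rng_batch.integers(0, n_frames, size=b)
        ys = self.rng_batch.integers(0, H - self.crop + 1, size=b)
        xs = self.rng_batch.integers(0, W - self.crop + 1, size=b)
        return idx, ys, xs

    def crop_frames(self, idx, ys, xs):
        c = self.crop
        return np.stack([self.frames[i, y:y + c, x:x + c]
                         for i, y, x in zip(idx, ys, xs)])[:, None]

    @staticmethod
    def crop_labels(labelmaps, idx, ys, xs, c):
        return np.stack([labelmaps[i, y:y + c, x:x + c]
                         for i, y, x in zip(idx, ys, xs)])

    def step(self, xb, head_labels, head_masks=None, head_scales=None):
        """One gradient step.

        ``head_labels`` is a list with one (B, h, w) label array per head
        (None to skip a head); ``head_masks`` optional per-head (B,) bools;
        ``head_scales`` optional per-head loss multipliers (used to weight
        the heads' supervision streams equally regardless of how many
        batch samples each head received). Returns the summed loss.
        """
        it = len(self.loss_history)
        self.adam.lr = (self.cfg.lr_initial if it < self.cfg.lr_switch_iter
                        else self.cfg.lr_after)
        self.model.zero_grad()
        scores = self.model.forward(xb, train=True)
        grads = []
        total = 0.0
        head_losses = []
        for h, labels in enumerate(head_labels):
            if labels is None:
                grads.append(None)
                head_losses.append(0.0)
                continue
            mask = None if head_masks is None else head_masks[h]
            loss, g = cross_entropy_loss_grad(
                scores[h], labels, class_weights=self.cfg.class_weights,
                sample_mask=mask)
            if head_scales is not None and head_scales[h] != 1.0:
                loss *= head_scales[h]
                g = g * head_scales[h]
            grads.append(g)
            head_losses.append(loss)
            total += loss
        self.model.backward(grads)
        self.adam.step()
        self.loss_history.append(total)
        self.last_head_losses = head_losses
        return total


def train_single_source(frames, source, model: DetectorModel,
                        cfg: TrainConfig):
    """Train on one annotation source; returns (model, loss_history).

    With ``total_iters=0`` the model is returned at its initialization.
    """
    labels = source.labelmaps if isinstance(source, AnnotationSource) else source
    labels = _check_labels(labels, model.n_classes)
    frames = _as_frames(frames)
    if labels.shape != frames.shape:
        raise ValueError("one label map per frame of matching shape required")
    eng = _SGDEngine(frames, model, cfg)
    for _ in range(cfg.total_iters):
        idx, ys, xs = eng.sample_batch()
        xb = eng.crop_frames(idx, ys, xs)
        yb = eng.crop_labels(labels, idx, ys, xs, eng.crop)
        eng.step(xb, [yb] + [None] * (model.n_heads - 1))
    return model, eng.loss_history


def _student_distances(model, xb, label_crops, distance):
    """Per-sample distance between the student's prediction and each
    annotation version: (B, K) array."""
    scores = model.forward(xb, train=False)[0]
    probs = softmax(scores, axis=1)
    B = xb.shape[0]
    K = len(label_crops)
    d = np.empty((B, K))
    logp = np.log(np.clip(probs, 1e-12, None))
    for k, yk in enumerate(label_crops):
        if distance == "pixel_ce":
            picked = np.take_along_axis(logp, yk[:, None], axis=1)[:, 0]
            d[:, k] = -picked.mean(axis=(1, 2))
        else:  # l1_prob
            onehot = np.zeros_like(probs)
            np.put_along_axis(onehot, yk[:, None], 1.0, axis=1)
            d[:, k] = np.abs(probs - onehot).mean(axis=(1, 2, 3))
    return d


def _selection_probs(d, temperature):
    """softmax(-d / temperature) per sample, in float64 for stability."""
    z = -d / temperature
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _run_multi_source(frames, sources, model, cfg, select_fn, sel_seed):
    """Shared loop for the multi-source trainers.

    ``select_fn(it, d, rng) -> (choice, probs)`` maps per-sample distances
    to a selected source index per sample.
    """
    if not sources:
        raise ValueError("at least one annotation source required")
    label_stacks = [
        _check_labels(s.labelmaps if isinstance(s, AnnotationSource) else s,
                      model.n_classes)
        for s in sources]
    frames = _as_frames(frames)
    for ls in label_stacks:
        if ls.shape != frames.shape:
            raise ValueError("all sources must cover the same frames with "
                             "matching shapes")
    eng = _SGDEngine(frames, model, cfg)
    rng_sel = np.random.default_rng(np.random.SeedSequence(sel_seed))
    selection_log = []
    K = len(label_stacks)
    for it in range(cfg.total_iters):
        idx, ys, xs = eng.sample_batch()
        xb = eng.crop_frames(idx, ys, xs)
        crops = [eng.crop_labels(ls, idx, ys, xs, eng.crop)
                 for ls in label_stacks]
        choice, probs = select_fn(it, eng, xb, crops, rng_sel)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9), \
            "selection probabilities must sum to 1 per sample"
        yb = np.stack([crops[k][b] for b, k in enumerate(choice)])
        eng.step(xb, [yb] + [None] * (model.n_heads - 1))
        selection_log.append({
            "iteration": it,
            "counts": np.bincount(choice, minlength=K).tolist(),
            "mean_probs": probs.mean(axis=0).tolist(),
        })
    return model, eng.loss_history, selection_log


def train_probabilistic_nn_fit(frames, sources, model: DetectorModel,
                               cfg: TrainConfig,
                               ecfg: EnsembleConfig = EnsembleConfig()):
    """Probabilistic NN-Fit distillation; returns
    (model, loss_history, selection_log)."""
    K = len(sources)

    def select(it, eng, xb, crops, rng):
        if it < ecfg.warmup_iters:
            probs = np.full((xb.shape[0], K), 1.0 / K)
        else:
            d = _student_distances(eng.model, xb, crops, ecfg.distance)
            probs = _selection_probs(d, ecfg.temperature)
        choice = np.array([rng.choice(K, p=p) for p in probs])
        return choice, probs

    return _run_multi_source(frames, sources, model, cfg, select, ecfg.seed)


def train_random_nn_fit(frames, sources, model: DetectorModel,
                        cfg: TrainConfig, switch_iter: int,
                        distance: str = "pixel_ce", sel_seed: int = 0):
    """Two-stage Random/NN-Fit baseline: uniform selection before
    ``switch_iter``, greedy minimum-distance selection after."""
    K = len(sources)

    def select(it, eng, xb, crops, rng):
        B = xb.shape[0]
        if it < switch_iter:
            probs = np.full((B, K), 1.0 / K)
            choice = np.array([rng.choice(K, p=p) for p in probs])
        else:
            d = _student_distances(eng.model, xb, crops, distance)
            choice = d.argmin(axis=1)           # ties -> lower source index
            probs = np.zeros((B, K))
            probs[np.arange(B), choice] = 1.0
            rng.random(B)  # keep the selection stream in lockstep
        return choice, probs

    return _run_multi_source(frames, sources, model, cfg, select, sel_seed)


def train_hybrid(frames, aa_source, ha_source, model: DetectorModel,
                 cfg: TrainConfig, aa_indices=None, ha_indices=None,
                 head_weighting: str = "equal"):
    """Two-headed training on algorithm + human annotations.

    ``aa_indices`` / ``ha_indices`` name the frames covered by each source
    (defaults: all frames). Each batch samples uniformly from the union of
    (frame, source) pairs; algorithm samples contribute loss only through
    head 1 and human samples only through head 2, while the shared trunk
    learns from both. An empty human pool degenerates (documented, not an
    error) to single-source training through head 1.

    ``head_weighting`` sets how the two supervision streams combine:
    ``"equal"`` (default) weights each head's loss as the mean over its
    own samples, so the objective is the sum of an algorithm-annotation
    loss and a human-annotation loss with equal say regardless of pool
    sizes; ``"proportional"`` weights every batch sample equally, letting
    the larger pool dominate the shared trunk in proportion to its size.

    Returns (model, loss_history, head_loss_history) where
    ``head_loss_history`` is a list of (head1_loss, head2_loss) tuples.
    """
    if head_weighting not in ("equal", "proportional"):
        raise ValueError("head_weighting must be 'equal' or 'proportional'")
    if model.n_heads != 2:
        raise ValueError("train_hybrid requires a two-headed model")
    frames = _as_frames(frames)
    N = frames.shape[0]
    aa_indices = np.arange(N) if aa_indices is None else np.asarray(aa_indices)
    ha_indices = np.arange(N) if ha_indices is None else np.asarray(ha_indices)

    def _labels(src):
        if src is None:
            return None
        lm = src.labelmaps if isinstance(src, AnnotationSource) else src
        return _check_labels(lm, model.n_classes)

    aa_labels = _labels(aa_source)
    ha_labels = _labels(ha_source)
    if aa_labels is None or len(aa_indices) == 0:
        aa_indices = np.zeros(0, dtype=int)
    if ha_labels is None or len(ha_indices) == 0:
        ha_indices = np.zeros(0, dtype=int)
    pool = ([(i, 0) for i in aa_indices] + [(i, 1) for i in ha_indices])
    if not pool:
        raise ValueError("at least one annotated frame required")
    pool_frames = np.array([p[0] for p in pool])
    pool_heads = np.array([p[1] for p in pool])

    eng = _SGDEngine(frames, model, cfg)
    head_losses = []
    for _ in range(cfg.total_iters):
        pick, ys, xs = eng.sample_batch(n_frames=len(pool))
        idx = pool_frames[pick]
        heads = pool_heads[pick]
        xb = eng.crop_frames(idx, ys, xs)
        yb1 = (eng.crop_labels(aa_labels, idx, ys, xs, eng.crop)
               if aa_labels is not None else None)
        yb2 = (eng.crop_labels(ha_labels, idx, ys, xs, eng.crop)
               if ha_labels is not None else None)
        masks = [heads == 0, heads == 1]
        scales = None
        if head_weighting == "equal":
            B = len(heads)
            scales = [B / max(int(m.sum()), 1) if m.any() else 1.0
                      for m in masks]
        eng.step(xb, [yb1, yb2], head_masks=masks, head_scales=scales)
        head_losses.append(tuple(eng.last_head_losses))
    return model, eng.loss_history, head_losses


def make_network_sources(frames, teachers, names=None):
    """Teacher predictions as annotation sources (hard argmax maps)."""
    frames = _as_frames(frames)
    names = names or [f"teacher_{i}" for i in range(len(teachers))]
    sources = []
    for name, teacher in zip(names, teachers):
        lm = predict_labelmap(teacher, frames, fuse="head1")
        sources.append(AnnotationSource(name=name, labelmaps=lm,
                                        origin="network"))
    return sources


def average_ensemble_predict(teachers, frames, batch_size=8):
    """Average-Ensemble baseline: mean of the teachers' probability maps,
    then argmax (ties toward the lower class index)."""
    if not teachers:
        raise ValueError("at least one teacher required")
    acc = None
    for teacher in teachers:
        probs = predict_proba(teacher, frames, batch_size=batch_size)[0]
        acc = probs if acc is None else acc + probs
    return np.argmax(acc / len(teachers), axis=-1).astype(np.uint8)


def render_human_annotation(centers_per_frame, shape, disk_radius: int = 3,
                            boundary_radius: int = 2) -> np.ndarray:
    """Convert per-frame center points into dense three-class label maps.

    Each center becomes a disk of ``disk_radius`` (class 1; exactly the
    pixels within Euclidean distance <= radius of the center) with a
    dilation ring (class 2). Out-of-bounds centers are clipped to the
    frame with a warning.
    """
    import warnings

    H, W = shape
    N = len(centers_per_frame)
    out = np.zeros((N, H, W), dtype=np.uint8)
    fp = _disk_footprint(boundary_radius) if boundary_radius > 0 else None
    rows, cols = np.ogrid[:H, :W]
    for t, centers in enumerate(centers_per_frame):
        centers = np.asarray(centers, dtype=float).reshape(-1, 2)
        body = np.zeros((H, W), dtype=bool)
        for x, y in centers:
            if not (0 <= x < W and 0 <= y < H):
                warnings.warn(f"center ({x:.1f}, {y:.1f}) outside the "
                              f"{H}x{W} frame; disk clipped", stacklevel=2)
            body |= (rows - y) ** 2 + (cols - x) ** 2 <= disk_radius ** 2
        if fp is not None:
            ring = _dilation(body, fp) & ~body
            out[t][ring] = 2
        out[t][body] = 1
    return out
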