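"""Synthetic ant-video generator with ground-truth centers.

Emulates the conditions of night-time ant surveillance footage at desk
scale: a static textured background, elongated dark "ants" performing
bounded random walks, plus the two label-noise regimes that motion-based
pseudo-annotation suffers from —

* *systematic* errors: non-ant moving distractors that any motion cue will
  consistently flag as foreground (they are excluded from the ground-truth
  centers on purpose);
* *non-systematic* errors: transient "wind" events in which the background
  layer alone is displaced for a single frame, producing spurious motion
  that is inconsistent across visually identical frames.

Determinism contract: identical ``SynthConfig`` (including ``seed``)
produces bit-identical frames and centers. The random state is split into
six named child streams (placement, walk, distractor-walk, wind, texture,
noise) via ``np.random.SeedSequence(seed).spawn(6)``, in that order, so
individual mechanisms can be replayed independently.

Random-walk update rule (replayable): for each frame t >= 1 and each
walker j in index order, draw ``dx = normal(0, step_sigma)`` then
``dy = normal(0, step_sigma)`` from the walk stream, add to the position,
and reflect each coordinate into ``[margin, size - 1 - margin]``. The
heading is the angle of the post-reflection displacement (unchanged when
the displacement is zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as _draw_disk
from skimage.draw import ellipse as _draw_ellipse
from skimage.morphology import dilation as _dilation, disk as _disk_footprint

__all__ = [
    "SynthConfig",
    "SyntheticVideo",
    "PlacementError",
    "generate_video",
    "rasterize_gt_labelmap",
    "reflect",
]


class PlacementError(RuntimeError):
    """Raised when initial non-overlapping placement fails after retries."""


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic clip.

    Intensities are floats in [0, 1]; ants are darker than the background
    by default (``ant_intensity_offset < 0``), matching night footage of
    dark-bodied ants. ``ant_axes`` are the (major, minor) semi-axis lengths
    of the ant ellipse in pixels.
    """

    frame_height: int = 64
    frame_width: int = 64
    n_frames: int = 48
    n_ants: int = 3
    ant_axes: tuple[float, float] = (4.0, 2.0)
    ant_intensity_offset: float = -0.35
    step_sigma: float = 2.5
    n_distractors: int = 1
    distractor_shape: str = "disk"
    wind_prob: float = 0.15
    wind_magnitude: float = 2.0
    background_texture_sigma: float = 0.08
    background_level: float = 0.55
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.frame_height, self.frame_width, self.n_frames) < 1:
            raise ValueError("frame dims and n_frames must be positive")
        if self.n_ants < 0 or self.n_distractors < 0:
            raise ValueError("counts must be >= 0")
        if min(self.ant_axes) < 1:
            raise ValueError("ant axes must be >= 1 px")
        if not 0.0 <= self.wind_prob <= 1.0:
            raise ValueError("wind_prob must be in [0, 1]")
        if self.distractor_shape not in ("disk", "square"):
            raise ValueError("distractor_shape must be 'disk' or 'square'")


@dataclass
class SyntheticVideo:
    """Frames plus per-frame ground truth.

    ``gt_centers[t]`` is an (n_ants, 2) float array of (x, y) ant centers —
    distractors are never included. ``distractor_centers`` is kept for
    diagnostics only.
    """

    frames: np.ndarray                       # (N, H, W) float in [0, 1]
    gt_centers: list[np.ndarray]             # per frame, (n, 2) as (x, y)
    gt_headings: list[np.ndarray]            # per frame, (n,) radians
    distractor_centers: list[np.ndarray]
    config: SynthConfig = field(default=None)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def reflect(v: float, lo: float, hi: float) -> float:
    """Reflect a scalar into [lo, hi] (billiard boundary)."""
    if hi <= lo:
        return lo
    period = 2.0 * (hi - lo)
    w = (v - lo) % period
    return lo + w if w <= hi - lo else lo + period - w


def _margin(cfg: SynthConfig) -> float:
    return float(math.ceil(max(cfg.ant_axes)) + 1)


def _place(rng, n, cfg, existing, min_sep):
    """Uniform non-overlapping initial positions; bounded retries."""
    m = _margin(cfg)
    placed = list(existing)
    out = []
    for _ in range(n):
        for _attempt in range(500):
            x = rng.uniform(m, cfg.frame_width - 1 - m)
            y = rng.uniform(m, cfg.frame_height - 1 - m)
            if all((x - px) ** 2 + (y - py) ** 2 >= min_sep ** 2
                   for px, py in placed):
                placed.append((x, y))
                out.append((x, y))
                break
        else:
            raise PlacementError(
                f"could not place {n} objects without overlap in a "
                f"{cfg.frame_height}x{cfg.frame_width} frame")
    return out


def _simulate_walks(rng, starts, headings0, cfg):
    """Shared random-walk simulator for ants and distractors.

    Returns (positions, headings): lists over frames of (n, 2) xy arrays
    and (n,) heading arrays. Consumes exactly 2 normal draws per walker
    per frame (dx then dy), in walker index order.
    """
    m = _margin(cfg)
    xs = [np.array(starts, dtype=float).reshape(-1, 2)]
    hs = [np.array(headings0, dtype=float).reshape(-1)]
    n = xs[0].shape[0]
    for _t in range(1, cfg.n_frames):
        prev = xs[-1]
        prev_h = hs[-1]
        cur = np.empty_like(prev)
        cur_h = prev_h.copy()
        for j in range(n):
            dx = rng.normal(0.0, cfg.step_sigma)
            dy = rng.normal(0.0, cfg.step_sigma)
            nx = reflect(prev[j, 0] + dx, m, cfg.frame_width - 1 - m)
            ny = reflect(prev[j, 1] + dy, m, cfg.frame_height - 1 - m)
            ddx, ddy = nx - prev[j, 0], ny - prev[j, 1]
            if ddx != 0.0 or ddy != 0.0:
                cur_h[j] = math.atan2(ddy, ddx)
            cur[j] = (nx, ny)
        xs.append(cur)
        hs.append(cur_h)
    return xs, hs


def _ant_pixels(center_xy, axes, heading, shape):
    """Pixel coordinates (rr, cc) of an oriented ant ellipse, clipped."""
    x, y = center_xy
    major, minor = axes
    return _draw_ellipse(y, x, minor, major, shape=shape, rotation=heading)


def _distractor_pixels(center_xy, radius, shape_kind, shape):
    x, y = center_xy
    if shape_kind == "disk":
        return _draw_disk((y, x), radius + 0.5, shape=shape)
    r0 = max(int(round(y - radius)), 0)
    r1 = min(int(round(y + radius)) + 1, shape[0])
    c0 = max(int(round(x - radius)), 0)
    c1 = min(int(round(x + radius)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return rr.ravel(), cc.ravel()


def generate_video(config: SynthConfig) -> SyntheticVideo:
    """Generate one clip with per-frame ground-truth ant centers.

    Ants and distractors follow independent bounded random walks; with
    probability ``wind_prob`` a frame's background layer (only) is
    displaced by ``wind_magnitude`` pixels for that single frame and then
    restored, leaving the ants in place — the transient false-motion event.
    """
    cfg = config
    H, W = cfg.frame_height, cfg.frame_width
    ss = np.random.SeedSequence(cfg.seed)
    rng_place, rng_walk, rng_dwalk, rng_wind, rng_texture, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(6))

    min_sep = 2.0 * max(cfg.ant_axes) + 1.0
    ant_starts = _place(rng_place, cfg.n_ants, cfg, [], min_sep)
    distr_starts = _place(rng_place, cfg.n_distractors, cfg, ant_starts, min_sep)
    ant_h0 = [rng_place.uniform(0, 2 * math.pi) for _ in range(cfg.n_ants)]
    distr_h0 = [rng_place.uniform(0, 2 * math.pi)
                for _ in range(cfg.n_distractors)]

    ant_pos, ant_head = _simulate_walks(rng_walk, ant_starts, ant_h0, cfg)
    distr_pos, _ = _simulate_walks(rng_dwalk, distr_starts, distr_h0, cfg)

    # one wind decision (+ direction draw when triggered) per frame
    wind_offsets = []
    for _t in range(cfg.n_frames):
        if rng_wind.uniform() < cfg.wind_prob and cfg.wind_magnitude > 0:
            direction = rng_wind.integers(0, 8)
            angle = direction * math.pi / 4.0
            dy = int(round(cfg.wind_magnitude * math.sin(angle)))
            dx = int(round(cfg.wind_magnitude * math.cos(angle)))
            if dy == 0 and dx == 0:
                dx = int(round(cfg.wind_magnitude)) or 1
            wind_offsets.append((dy, dx))
        else:
            wind_offsets.append(None)

    background = (cfg.background_level
                  + cfg.background_texture_sigma
                  * rng_texture.standard_normal((H, W)))

    radius = float(min(cfg.ant_axes))
    frames = np.empty((cfg.n_frames, H, W), dtype=np.float64)
    for t in range(cfg.n_frames):
        off = wind_offsets[t]
        bg = background if off is None else np.roll(background, off, axis=(0, 1))
        img = bg.copy()
        for j in range(cfg.n_distractors):
            rr, cc = _distractor_pixels(distr_pos[t][j], radius,
                                        cfg.distractor_shape, (H, W))
            img[rr, cc] = bg[rr, cc] + cfg.ant_intensity_offset
        for j in range(cfg.n_ants):
            rr, cc = _ant_pixels(ant_pos[t][j], cfg.ant_axes, ant_head[t][j],
                                 (H, W))
            img[rr, cc] = bg[rr, cc] + cfg.ant_intensity_offset
        if cfg.noise_sigma > 0:
            img = img + cfg.noise_sigma * rng_noise.standard_normal((H, W))
        frames[t] = np.clip(img, 0.0, 1.0)

    return SyntheticVideo(
        frames=frames,
        gt_centers=[p.copy() for p in ant_pos],
        gt_headings=[h.copy() for h in ant_head],
        distractor_centers=[p.copy() for p in distr_pos],
        config=cfg,
    )


def rasterize_gt_labelmap(video: SyntheticVideo, boundary_radius: int = 2
                          ) -> np.ndarray:
    """Clean dense labels from ground truth: ant ellipses -> class 1, a
    dilation ring of the given radius -> class 2, rest class 0.

    Provides "human-quality" dense supervision for controlled experiments.
    Returns an (N, H, W) uint8 array.
    """
    cfg = video.config
    N, H, W = video.frames.shape
    out = np.zeros((N, H, W), dtype=np.uint8)
    fp = _disk_footprint(boundary_radius) if boundary_radius > 0 else None
    for t in range(N):
        body = np.zeros((H, W), dtype=bool)
        for j in range(len(video.gt_centers[t])):
            rr, cc = _ant_pixels(video.gt_centers[t][j], cfg.ant_axes,
                                 video.gt_headings[t][j], (H, W))
            body[rr, cc] = True
        lm = np.zeros((H, W), dtype=np.uint8)
        if fp is not None:
            ring = _dilation(body, fp) & ~body
            lm[ring] = 2
        lm[body] = 1
        out[t] = lm
    return out
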