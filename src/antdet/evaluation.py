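"""Point-detection scoring by maximum bipartite matching.

Predicted dense label maps are reduced to center points (centroids of
ant-body connected components), and predictions are scored against
ground-truth centers: a ground-truth point and a predicted point may be
matched when their Euclidean distance is at most ``dist_threshold``
(default 5 px, inclusive), and the overall pairing is a globally optimal
maximum-cardinality one-to-one matching (Hopcroft–Karp). Precision,
recall and F1 follow from the matched count. Among maximum matchings no
secondary distance minimization is applied — cardinality alone determines
the scores, so the choice among ties is score-irrelevant.

Degenerate convention (documented, configurable at call sites that expose
it): when both the ground-truth and predicted sets are empty, precision =
recall = F1 = 1.0 (a perfect empty scene); an empty prediction set against
non-empty ground truth scores 0.

Aggregation over the frames of a video is micro-averaged: matched/pred/gt
counts are summed over frames before computing P/R/F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching
from scipy.spatial.distance import cdist
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "MatchResult",
    "compute_prf",
    "match_centers",
    "labelmap_to_centers",
    "evaluate_video",
]


@dataclass
class MatchResult:
    """One-to-one matching between ground-truth and predicted centers.

    ``matched_pairs`` holds the explicit pairing for a single-frame
    match; aggregated (multi-frame) results carry pooled counts with an
    empty pair list.
    """

    matched_pairs: list[tuple[int, int]]
    n_gt: int
    n_pred: int
    precision: float
    recall: float
    f1: float
    dist_threshold: float = 5.0
    n_matched: int = 0

    def to_dict(self) -> dict:
        return dict(n_matched=self.n_matched, n_gt=self.n_gt,
                    n_pred=self.n_pred, precision=self.precision,
                    recall=self.recall, f1=self.f1,
                    dist_threshold=self.dist_threshold)


def compute_prf(n_matched: int, n_pred: int, n_gt: int,
                empty_scene_score: float = 1.0):
    """Precision, recall and F1 from match counts.

    P = matched/pred, R = matched/gt, F1 = 2PR/(P+R). When a denominator
    is zero: an empty prediction AND empty ground truth scores
    ``empty_scene_score`` (default 1.0) on all three; an empty prediction
    against non-empty ground truth has P = 0, and vice versa for R.
    """
    if n_matched < 0 or n_pred < 0 or n_gt < 0:
        raise ValueError("counts must be non-negative")
    if n_matched > min(n_pred, n_gt):
        raise ValueError(
            f"n_matched={n_matched} exceeds min(n_pred={n_pred}, n_gt={n_gt})")
    if n_pred == 0 and n_gt == 0:
        s = float(empty_scene_score)
        return s, s, s
    precision = n_matched / n_pred if n_pred > 0 else 0.0
    recall = n_matched / n_gt if n_gt > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return precision, recall, f1


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y)")
    return pts


def match_centers(gt, pred, dist_threshold: float = 5.0,
                  empty_scene_score: float = 1.0) -> MatchResult:
    """Maximum-cardinality matching of gt to predicted centers.

    Builds the bipartite graph of all gt–pred pairs with Euclidean
    distance <= ``dist_threshold`` and solves it with Hopcroft–Karp,
    which is globally optimal in cardinality (a greedy nearest-neighbour
    pairing is not).
    """
    if dist_threshold <= 0:
        raise ValueError("dist_threshold must be > 0")
    gt = _as_points(gt)
    pred = _as_points(pred)
    pairs: list[tuple[int, int]] = []
    if len(gt) and len(pred):
        adj = (cdist(gt, pred) <= dist_threshold)
        if adj.any():
            match = maximum_bipartite_matching(
                csr_matrix(adj.astype(np.int8)), perm_type="column")
            pairs = [(gi, int(pi)) for gi, pi in enumerate(match) if pi >= 0]
    p, r, f1 = compute_prf(len(pairs), len(pred), len(gt),
                           empty_scene_score=empty_scene_score)
    return MatchResult(matched_pairs=pairs, n_gt=len(gt), n_pred=len(pred),
                       precision=p, recall=r, f1=f1,
                       dist_threshold=dist_threshold, n_matched=len(pairs))


def labelmap_to_centers(labelmap, min_area: int = 5, connectivity: int = 8
                        ) -> np.ndarray:
    """Centroids of ant-body (class 1) connected components.

    Components smaller than ``min_area`` pixels are dropped.
    ``connectivity`` is 4 or 8 (pixel neighbourhood). Returns an (n, 2)
    float array of (x, y) = (column, row) centroids, sub-pixel.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lm = np.asarray(labelmap)
    if lm.ndim != 2:
        raise ValueError("labelmap_to_centers expects a single 2-D map")
    comp = cc_label(lm == 1, connectivity=1 if connectivity == 4 else 2)
    centers = [prop.centroid for prop in regionprops(comp)
               if prop.area >= min_area]
    if not centers:
        return np.zeros((0, 2))
    rc = np.asarray(centers, dtype=float)
    return rc[:, ::-1].copy()  # (row, col) -> (x, y)


def evaluate_video(gt_per_frame, pred_per_frame, dist_threshold: float = 5.0,
                   return_per_frame: bool = False,
                   empty_scene_score: float = 1.0):
    """Micro-averaged detection scores over the frames of a video.

    Each frame is matched independently; matched/pred/gt counts are summed
    and P/R/F1 are computed from the pooled counts.
    """
    if len(gt_per_frame) != len(pred_per_frame):
        raise ValueError(
            f"frame count mismatch: {len(gt_per_frame)} gt vs "
            f"{len(pred_per_frame)} pred")
    per_frame = [match_centers(g, p, dist_threshold,
                               empty_scene_score=empty_scene_score)
                 for g, p in zip(gt_per_frame, pred_per_frame)]
    n_matched = sum(m.n_matched for m in per_frame)
    n_pred = sum(m.n_pred for m in per_frame)
    n_gt = sum(m.n_gt for m in per_frame)
    p, r, f1 = compute_prf(n_matched, n_pred, n_gt,
                           empty_scene_score=empty_scene_score)
    # the aggregate result carries pooled counts; pairs stay per-frame
    agg = MatchResult(matched_pairs=[], n_gt=n_gt, n_pred=n_pred,
                      precision=p, recall=r, f1=f1,
                      dist_threshold=dist_threshold, n_matched=n_matched)
    if return_per_frame:
        return agg, per_frame
    return agg
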