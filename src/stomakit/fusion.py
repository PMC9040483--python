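"""Probability-map fusion, peak detection, and MCC-driven tuning.

The nine per-learner maps are combined as a pixel-wise weighted mean,
Gaussian-filtered, and local probability peaks above a height threshold
become stoma detections.  Agreement with human annotations is scored by
the Matthews correlation coefficient over a point-matching confusion
table, and a Nelder–Mead simplex adjusts the filter width and the height
threshold to maximize mean MCC over the training images.

True negatives have no natural definition for point detection; here they
are the rejected candidate peaks (local maxima below the threshold) that
do not fall near any annotated stoma, which makes the MCC computable and
penalizes thresholds that reject real stomata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial import cKDTree

from .synthetic import AnnotationSet

logger = logging.getLogger(__name__)

__all__ = [
    "FusionParams",
    "DetectionSet",
    "ConfusionCounts",
    "combine_maps",
    "smooth_map",
    "find_peaks",
    "match_points",
    "mcc",
    "tune_fusion",
    "flag_close_pairs",
]


@dataclass
class FusionParams:
    """Tunable fusion stage: per-learner weights, filter width, peak rules."""

    weights: np.ndarray = field(default_factory=lambda: np.full(9, 1.0 / 9.0))
    smooth_sigma_px: float = 2.0
    height_threshold: float = 0.5
    min_separation_px: float = 12.0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if self.smooth_sigma_px < 0:
            raise ValueError("smooth_sigma_px must be non-negative")
        if not (0 < self.height_threshold < 1):
            raise ValueError("height_threshold must be in (0, 1)")
        if self.min_separation_px <= 0:
            raise ValueError("min_separation_px must be positive")


@dataclass
class DetectionSet:
    """Detected stoma centers with fused heights and proximity flags.

    ``rejected`` holds sub-threshold candidate peaks; they feed the
    true-negative count when scoring against annotations.
    """

    points: np.ndarray
    heights: np.ndarray
    close_flags: np.ndarray | None = None
    rejected: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.heights = np.asarray(self.heights, dtype=float).ravel()
        self.rejected = np.asarray(self.rejected, dtype=float).reshape(-1, 2)
        if self.close_flags is None:
            self.close_flags = np.zeros(len(self.points), dtype=bool)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int
    match_radius_px: float

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be non-negative")


def write_probability_map(path, prob_map: np.ndarray) -> None:
    """Write a probability map as 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(prob_map, dtype=np.float32))


def read_probability_map(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(path), dtype=np.float32)


def combine_maps(maps: list[np.ndarray], weights: np.ndarray | None = None) -> np.ndarray:
    """Pixel-wise weighted mean of probability maps (weights renormalized)."""
    if not maps:
        raise ValueError("no maps to combine")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"maps have mismatched dimensions: {shapes}")
    if weights is None:
        weights = np.full(len(maps), 1.0 / len(maps))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(maps):
        raise ValueError("one weight per map required")
    if (weights < 0).any():
        raise ValueError("weights must be non-negative")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    if abs(total - 1.0) > 1e-9:
        logger.warning("weights sum to %.6g; renormalizing", total)
        weights = weights / total
    out = np.zeros_like(maps[0], dtype=float)
    for w, m in zip(weights, maps):
        out += w * np.asarray(m, dtype=float)
    return np.clip(out, 0.0, 1.0)


def smooth_map(prob_map: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian filtering with reflective boundary; sigma 0 is the identity."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be non-negative")
    if sigma_px == 0:
        return np.asarray(prob_map, dtype=float).copy()
    out = ndimage.gaussian_filter(np.asarray(prob_map, dtype=float), sigma=sigma_px, mode="reflect")
    return np.clip(out, 0.0, 1.0)


def _local_maxima(prob_map: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Candidate peaks: 8-connected local maxima with at least one strictly
    lower neighbor (flat plateaus such as the zero border band are not
    candidates), as (rows, cols)."""
    maxf = ndimage.maximum_filter(prob_map, size=3, mode="constant", cval=-np.inf)
    minf = ndimage.minimum_filter(prob_map, size=3, mode="constant", cval=np.inf)
    mask = (prob_map >= maxf) & (prob_map > minf) & (prob_map > 0)
    return np.nonzero(mask)


def find_peaks(
    prob_map: np.ndarray, height_threshold: float, min_separation_px: float
) -> DetectionSet:
    """Local maxima at or above the threshold, greedily accepted in
    decreasing height with an exclusion radius; ties broken by (row, col).
    """
    if not (0 < height_threshold < 1):
        raise ValueError("height_threshold must be in (0, 1)")
    if min_separation_px <= 0:
        raise ValueError("min_separation_px must be positive")
    prob_map = np.asarray(prob_map, dtype=float)
    rows, cols = _local_maxima(prob_map)
    heights = prob_map[rows, cols]
    above = heights >= height_threshold
    rej_rows, rej_cols = rows[~above], cols[~above]
    rows, cols, heights = rows[above], cols[above], heights[above]
    order = np.lexsort((cols, rows, -heights))
    accepted: list[int] = []
    min_sq = min_separation_px**2
    # cell hash with cell size = exclusion radius: only 3x3 neighborhood
    # of cells can contain a conflicting accepted peak
    cell = max(min_separation_px, 1.0)
    occupied: dict[tuple[int, int], list[tuple[float, float]]] = {}
    for idx in order:
        x, y = float(cols[idx]), float(rows[idx])
        ci, cj = int(y // cell), int(x // cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for ax, ay in occupied.get((ci + di, cj + dj), ()):
                    if (x - ax) ** 2 + (y - ay) ** 2 < min_sq:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(idx)
            occupied.setdefault((ci, cj), []).append((x, y))
    pts = np.array([[cols[i], rows[i]] for i in accepted], dtype=float).reshape(-1, 2)
    hts = heights[accepted] if accepted else np.empty(0)
    rejected = np.stack([rej_cols, rej_rows], axis=1).astype(float) if len(rej_rows) else np.empty((0, 2))
    return DetectionSet(points=pts, heights=hts, rejected=rejected)


def match_points(
    detections: DetectionSet, truth: AnnotationSet, match_radius_px: float
) -> ConfusionCounts:
    """Greedy one-to-one matching of detections to annotations by
    increasing pair distance within ``match_radius_px``.

    Matched pairs are TP; leftover detections FP; leftover annotations FN.
    TN counts the rejected (sub-threshold) candidate peaks not within the
    match radius of any annotation.
    """
    if match_radius_px <= 0:
        raise ValueError("match_radius_px must be positive")
    det = detections.points
    tru = np.asarray(truth.points, dtype=float).reshape(-1, 2)
    pairs: list[tuple[float, int, int]] = []
    if len(det) and len(tru):
        d = np.hypot(det[:, None, 0] - tru[None, :, 0], det[:, None, 1] - tru[None, :, 1])
        di, ti = np.nonzero(d <= match_radius_px)
        pairs = sorted(zip(d[di, ti], di, ti))
    used_det: set[int] = set()
    used_tru: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i not in used_det and j not in used_tru:
            used_det.add(i)
            used_tru.add(j)
            tp += 1
    fp = len(det) - tp
    fn = len(tru) - tp
    tn = 0
    rej = detections.rejected
    if len(rej):
        if len(tru):
            dr = np.hypot(rej[:, None, 0] - tru[None, :, 0], rej[:, None, 1] - tru[None, :, 1])
            tn = int((dr.min(axis=1) > match_radius_px).sum())
        else:
            tn = len(rej)
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn, match_radius_px=match_radius_px)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    if tp == tn == fp == fn == 0:
        raise ValueError("all-zero confusion counts")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom))


def flag_close_pairs(detections: DetectionSet, proximity_px: float) -> DetectionSet:
    """Flag every detection with a neighbor at distance ≤ proximity_px."""
    if proximity_px <= 0:
        raise ValueError("proximity_px must be positive")
    pts = detections.points
    flags = np.zeros(len(pts), dtype=bool)
    if len(pts) > 1:
        tree = cKDTree(pts)
        pairs = tree.query_pairs(proximity_px)
        for i, j in pairs:
            flags[i] = flags[j] = True
    return DetectionSet(
        points=pts.copy(),
        heights=detections.heights.copy(),
        close_flags=flags,
        rejected=detections.rejected.copy(),
    )


# ---------------------------------------------------------------------------
# Nelder--Mead tuning


def _detect(fused: np.ndarray, sigma: float, threshold: float, min_sep: float) -> DetectionSet:
    return find_peaks(smooth_map(fused, sigma), threshold, min_sep)


def detect_stomata(fused: np.ndarray, params: FusionParams) -> DetectionSet:
    """Smooth the fused map and pick peaks with the given parameters."""
    return _detect(fused, params.smooth_sigma_px, params.height_threshold, params.min_separation_px)


def mean_mcc(
    fused_maps: list[np.ndarray],
    truths: list[AnnotationSet],
    sigma: float,
    threshold: float,
    min_sep: float,
    match_radius_px: float,
) -> float:
    vals = []
    for fused, truth in zip(fused_maps, truths):
        det = _detect(fused, sigma, threshold, min_sep)
        counts = match_points(det, truth, match_radius_px)
        try:
            vals.append(mcc(counts))
        except ValueError:  # empty image and no candidates at all
            vals.append(0.0)
    return float(np.mean(vals))


def tune_fusion(
    maps_per_image: list[list[np.ndarray]],
    truths: list[AnnotationSet],
    init: FusionParams | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    match_radius_px: float = 20.0,
    optimize_weights: bool = False,
) -> tuple[FusionParams, float]:
    """Nelder–Mead over (smooth_sigma, height_threshold) maximizing mean MCC.

    The simplex runs in an unconstrained space (softplus for sigma, logit
    for the threshold).  With ``optimize_weights`` the per-learner fusion
    weights join the simplex through a log-softmax parameterization;
    by default they stay fixed at ``init.weights``.  The best parameter
    set ever evaluated — including the initial one — is returned, so the
    returned MCC never falls below the MCC at ``init``.  Deterministic
    given ``init``.
    """
    if init is None:
        init = FusionParams()
    if not maps_per_image or not any(len(t) for t in truths):
        raise ValueError("tuning requires at least one training image with annotations")
    init_weights = np.asarray(init.weights, dtype=float)
    init_weights = init_weights / init_weights.sum()
    n_maps = len(maps_per_image[0])
    fused_fixed = [combine_maps(maps, init_weights) for maps in maps_per_image]
    if max_iter == 0:
        score = mean_mcc(
            fused_fixed, truths, init.smooth_sigma_px, init.height_threshold,
            init.min_separation_px, match_radius_px,
        )
        return init, score

    def softplus(v: float) -> float:
        return float(np.log1p(np.exp(-abs(v))) + max(v, 0))

    def from_u(u):
        sigma = softplus(u[0])
        threshold = float(1.0 / (1.0 + np.exp(-u[1])))
        threshold = min(max(threshold, 1e-6), 1 - 1e-6)
        if optimize_weights:
            logits = np.asarray(u[2 : 2 + n_maps], dtype=float)
            ex = np.exp(logits - logits.max())
            weights = ex / ex.sum()
        else:
            weights = init_weights
        return sigma, threshold, weights

    def to_u():
        s = max(init.smooth_sigma_px, 1e-6)
        u0 = float(np.log(np.expm1(s))) if s < 30 else s
        t = min(max(init.height_threshold, 1e-6), 1 - 1e-6)
        u1 = float(np.log(t / (1 - t)))
        head = [u0, u1]
        if optimize_weights:
            head += list(np.log(np.maximum(init_weights, 1e-12)))
        return np.array(head)

    best = {
        "score": -np.inf,
        "sigma": init.smooth_sigma_px,
        "threshold": init.height_threshold,
        "weights": init_weights,
    }

    def objective(u):
        sigma, threshold, weights = from_u(u)
        if optimize_weights:
            fused = [combine_maps(maps, weights) for maps in maps_per_image]
        else:
            fused = fused_fixed
        score = mean_mcc(fused, truths, sigma, threshold, init.min_separation_px, match_radius_px)
        if score > best["score"]:
            best.update(score=score, sigma=sigma, threshold=threshold, weights=weights)
        return -score

    u0 = to_u()
    objective(u0)  # guarantees the ascent property vs init
    # scipy's default simplex perturbs by 5%, often below the MCC staircase
    # step; use steps that move each parameter by a meaningful amount
    simplex = [u0] + [u0 + np.eye(len(u0))[j] for j in range(len(u0))]
    optimize.minimize(
        objective,
        u0,
        method="Nelder-Mead",
        options={
            "maxiter": max_iter,
            "fatol": tol,
            "xatol": 1e-3,
            "initial_simplex": np.array(simplex),
            "disp": False,
        },
    )
    tuned = replace(
        init,
        weights=np.asarray(best["weights"], dtype=float),
        smooth_sigma_px=best["sigma"],
        height_threshold=best["threshold"],
    )
    return tuned, best["score"]
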