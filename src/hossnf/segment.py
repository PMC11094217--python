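"""HBO-driven multilevel-threshold segmentation.

The optimizer searches threshold space: n thresholds partition the 256-bin
gray histogram into n+1 classes and the objective scores the partition —
Kapur entropy (default: sum of within-class Shannon entropies, maximized) or
Otsu between-class variance.  With the darkest-class convention the most
intense hematoxylin staining (the nucleus) receives the highest label, so a
2-threshold search yields background/cytoplasm/nucleus masks directly.

An exhaustive search over integer threshold tuples is provided for small n;
it is the ground truth the stochastic search is measured against.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np

from . import heapopt
from .exceptions import ConfigError, InputError, SegmentationFailure
from .heapopt import HOConfig
from .imgio import validate_gray

logger = logging.getLogger(__name__)

OBJECTIVES = ("kapur", "otsu")


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing integer thresholds in [1, 254].

    A pixel with intensity v falls in class c when t_c < v <= t_{c+1}
    (t_0 = -1, t_{n+1} = 255); labels are then inverted so the darkest class
    gets the highest label (nucleus = darkest)."""

    thresholds: tuple[int, ...]

    def __post_init__(self) -> None:
        t = self.thresholds
        if not t:
            raise ConfigError("at least one threshold required")
        if any(not (1 <= v <= 254) for v in t):
            raise ConfigError(f"thresholds must lie in [1, 254], got {t}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ConfigError(f"thresholds must be strictly increasing, got {t}")

    @property
    def n_classes(self) -> int:
        return len(self.thresholds) + 1


def histogram256(img: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram; bins sum to the pixel count."""
    img = validate_gray(img)
    return np.bincount(img.ravel(), minlength=256)


# ---------------------------------------------------------------------------
# objectives (higher is better; the HBO minimizes the negation)
# ---------------------------------------------------------------------------

def _class_edges(thresholds: tuple[int, ...]) -> list[tuple[int, int]]:
    """(lo, hi] bin ranges per class, using lo = -1 sentinel for the first."""
    cuts = (-1,) + tuple(thresholds) + (255,)
    return list(zip(cuts[:-1], cuts[1:]))


def kapur_fitness(hist: np.ndarray, t: ThresholdSet) -> float:
    """Summed Kapur entropy of the histogram partition.

    For class c with probability mass w_c, H_c = -sum (p_i/w_c) ln(p_i/w_c)
    over its occupied bins; an empty class contributes 0."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total <= 0:
        raise InputError("empty histogram")
    p = hist / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    P = np.concatenate([[0.0], np.cumsum(p)])
    S = np.concatenate([[0.0], np.cumsum(plogp)])
    fit = 0.0
    for lo, hi in _class_edges(t.thresholds):
        w = P[hi + 1] - P[lo + 1]
        if w > 0:
            s = S[hi + 1] - S[lo + 1]
            fit += -(s / w) + np.log(w)
    return float(fit)


def otsu_fitness(hist: np.ndarray, t: ThresholdSet) -> float:
    """Between-class variance sum w_c (mu_c - mu)^2 of the partition."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    if total <= 0:
        raise InputError("empty histogram")
    p = hist / total
    levels = np.arange(256, dtype=float)
    mu = float(p @ levels)
    P = np.concatenate([[0.0], np.cumsum(p)])
    M = np.concatenate([[0.0], np.cumsum(p * levels)])
    fit = 0.0
    for lo, hi in _class_edges(t.thresholds):
        w = P[hi + 1] - P[lo + 1]
        if w > 0:
            mu_c = (M[hi + 1] - M[lo + 1]) / w
            fit += w * (mu_c - mu) ** 2
    return float(fit)


_OBJECTIVE_FNS = {"kapur": kapur_fitness, "otsu": otsu_fitness}


# ---------------------------------------------------------------------------
# searches
# ---------------------------------------------------------------------------

def _repair_thresholds(values: np.ndarray) -> tuple[int, ...]:
    """Round, sort and de-duplicate a continuous threshold vector into a
    strictly increasing integer tuple within [1, 254]."""
    t = sorted(int(round(v)) for v in values)
    n = len(t)
    t = [min(max(v, 1), 254) for v in t]
    for i in range(1, n):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1
    # ran off the top: walk back down
    for i in range(n - 1, -1, -1):
        cap = 254 - (n - 1 - i)
        if t[i] > cap:
            t[i] = cap
    return tuple(t)


def exhaustive_threshold_search(
    hist: np.ndarray, n_thresholds: int, objective: str = "kapur"
) -> tuple[ThresholdSet, float]:
    """Global optimum by enumerating integer threshold tuples.

    Only the set of occupied bins below each cut determines the partition,
    so the enumeration runs over two representatives per equivalence
    interval of cut positions (the interval's first two integers), which is
    exact for n_thresholds <= 2; for denser problems it falls back to the
    full integer range.
    """
    hist = np.asarray(hist)
    fn = _OBJECTIVE_FNS[objective]
    occupied = np.flatnonzero(hist)
    cand_set = {1}
    for o in occupied:
        cand_set.update((int(o), int(o) + 1))
    candidates = sorted(v for v in cand_set if 1 <= v <= 254)
    if len(candidates) < n_thresholds:
        candidates = list(range(1, 255))
    best_t, best_f = None, -np.inf
    for combo in itertools.combinations(candidates, n_thresholds):
        ts = ThresholdSet(combo)
        f = fn(hist, ts)
        if f > best_f:
            best_t, best_f = ts, f
    return best_t, best_f


def ho_threshold_search(
    img: np.ndarray,
    n_thresholds: int = 2,
    cfg: HOConfig | None = None,
    objective: str = "kapur",
    seed: int = 0,
    restarts: int = 8,
) -> tuple[ThresholdSet, float]:
    """HBO search for n_thresholds in [1, 4]; returns (thresholds, fitness).

    Positions live in continuous [1, 254]^n and are rounded/sorted/repaired
    before each objective evaluation.  The threshold landscape is piecewise
    constant with sizeable local plateaus, so the search is restarted
    ``restarts`` times from independently seeded populations and the best
    result kept (ties break toward the earliest restart).  A degenerate
    (single gray level) histogram short-circuits to evenly spaced thresholds
    with a warning.
    """
    if not (1 <= n_thresholds <= 4):
        raise ConfigError(f"n_thresholds must be in [1, 4], got {n_thresholds}")
    if objective not in OBJECTIVES:
        raise ConfigError(f"objective must be one of {OBJECTIVES}, got {objective!r}")
    hist = histogram256(img)
    if np.count_nonzero(hist) <= 1:
        logger.warning("degenerate histogram (single gray level); returning even thresholds")
        even = tuple(
            int(round(255 * (k + 1) / (n_thresholds + 1))) for k in range(n_thresholds)
        )
        ts = ThresholdSet(even)
        return ts, _OBJECTIVE_FNS[objective](hist, ts)

    fn = _OBJECTIVE_FNS[objective]

    def neg_objective(x: np.ndarray) -> float:
        return -fn(hist, ThresholdSet(_repair_thresholds(x)))

    if cfg is None:
        cfg = HOConfig(
            dimensions=n_thresholds, lower_bounds=1.0, upper_bounds=254.0,
            population_size=40, max_iterations=60, seed=seed,
        )
    sub_seeds = np.random.SeedSequence(cfg.seed).generate_state(max(1, restarts)) % (2**31)
    best = None
    for k, s in enumerate(sub_seeds):
        run_cfg = replace(cfg, seed=int(s) if k else cfg.seed)
        res = heapopt.optimize(neg_objective, run_cfg)
        if best is None or res.best_fitness < best.best_fitness:
            best = res
    ts = ThresholdSet(_repair_thresholds(best.best_position))
    return ts, -best.best_fitness


# ---------------------------------------------------------------------------
# mask construction and scoring
# ---------------------------------------------------------------------------

def apply_thresholds(img: np.ndarray, t: ThresholdSet) -> np.ndarray:
    """Label mask with the darkest class mapped to the highest label
    (3 classes: brightest -> 0 background, middle -> 1 cytoplasm,
    darkest -> 2 nucleus)."""
    img = validate_gray(img)
    cuts = np.asarray(t.thresholds)
    # searchsorted('left') = #{cuts < v}, i.e. the brightness-ordered class
    raw = np.searchsorted(cuts, img, side="left")
    return (len(t.thresholds) - raw).astype(np.uint8)


@dataclass(frozen=True)
class OverlapReport:
    dice: dict[int, float]
    iou: dict[int, float]
    pixel_accuracy: float


def overlap_metrics(pred: np.ndarray, truth: np.ndarray,
                    labels: tuple[int, ...] = (0, 1, 2)) -> OverlapReport:
    """Per-label Dice and IoU plus overall pixel accuracy.

    An empty-in-both label scores 1.0 (perfect vacuous agreement)."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise InputError(f"mask shape mismatch: {pred.shape} vs {truth.shape}")
    dice, iou = {}, {}
    for lab in labels:
        a = pred == lab
        b = truth == lab
        inter = int(np.count_nonzero(a & b))
        sa, sb = int(a.sum()), int(b.sum())
        if sa + sb == 0:
            dice[lab] = 1.0
            iou[lab] = 1.0
        else:
            dice[lab] = 2.0 * inter / (sa + sb)
            union = sa + sb - inter
            iou[lab] = inter / union if union else 1.0
    acc = float(np.count_nonzero(pred == truth)) / pred.size
    return OverlapReport(dice=dice, iou=iou, pixel_accuracy=acc)


def extract_roi(img: np.ndarray, mask: np.ndarray, margin: int = 0) -> np.ndarray:
    """Crop to the bounding box of the cell labels {1, 2} plus margin,
    clipped to the image."""
    img = validate_gray(img)
    if img.shape != mask.shape:
        raise InputError(f"image/mask shape mismatch: {img.shape} vs {mask.shape}")
    cell = (mask == 1) | (mask == 2)
    if not cell.any():
        raise SegmentationFailure("no cell pixels in mask; segmentation failed")
    rows = np.flatnonzero(cell.any(axis=1))
    cols = np.flatnonzero(cell.any(axis=0))
    r0 = max(0, rows[0] - margin)
    r1 = min(img.shape[0], rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(img.shape[1], cols[-1] + 1 + margin)
    return img[r0:r1, c0:c1]
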