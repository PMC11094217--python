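"""GLCM, LBP and Gabor texture features for segmented cell images.

The fixed 58-value feature vector concatenates, in order:

* 32 GLCM statistics — contrast, energy, entropy, correlation for every
  (distance, angle) pair with distances {1, 2} and angles {0, 45, 90, 135}
  degrees, distance-major / angle-minor;
* 10 uniform-LBP histogram bins (8 discrete neighbors, radius 1; nine
  uniform classes keyed by the number of set bits plus one non-uniform bin);
* 16 Gabor responses — mean and standard deviation of the absolute filter
  response for a 5x5 bank of 2 frequencies x 4 orientations,
  frequency-major.

GLCM co-occurrence counting is delegated to scikit-image; the Haralick
statistics themselves (including the sigma = 0 -> correlation = 1 convention
for constant images) are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from skimage.feature import graycomatrix

from .exceptions import ConfigError, InputError, ValidationError
from .imgio import validate_gray


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 8
    distances: tuple[int, ...] = (1, 2)
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ConfigError("GLCM levels must be >= 2")
        if any(d < 1 for d in self.distances):
            raise ConfigError("GLCM distances must be positive integers")


@dataclass(frozen=True)
class GaborBankConfig:
    kernel_size: int = 5
    frequencies: tuple[float, ...] = (0.3, 0.6)   # cycles / pixel
    orientations_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    sigma: float = 2.0
    phase_offset: float = 0.0
    aspect_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.kernel_size % 2 == 0:
            raise ConfigError("Gabor kernel side must be odd")

    @property
    def n_filters(self) -> int:
        return len(self.frequencies) * len(self.orientations_deg)


GLCM_STAT_NAMES = ("contrast", "energy", "entropy", "correlation")


def feature_names(glcm_cfg: GLCMConfig | None = None,
                  gabor_cfg: GaborBankConfig | None = None) -> list[str]:
    """Canonical ordered names of all 58 features."""
    glcm_cfg = glcm_cfg or GLCMConfig()
    gabor_cfg = gabor_cfg or GaborBankConfig()
    names = [
        f"glcm_d{d}_a{int(a)}_{stat}"
        for d in glcm_cfg.distances
        for a in glcm_cfg.angles_deg
        for stat in GLCM_STAT_NAMES
    ]
    names += [f"lbp_u{k}" for k in range(9)] + ["lbp_nonuniform"]
    names += [
        f"gabor_f{f}_o{int(a)}_{stat}"
        for f in gabor_cfg.frequencies
        for a in gabor_cfg.orientations_deg
        for stat in ("mean", "std")
    ]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(feature_names())
N_FEATURES = len(FEATURE_NAMES)  # 58


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniform re-quantization of [0, 255] into ``levels`` gray levels."""
    img = validate_gray(img)
    return ((img.astype(np.int64) * levels) // 256).astype(np.uint8)


def glcm(img: np.ndarray, distance: int, angle_deg: float,
         cfg: GLCMConfig | None = None) -> np.ndarray:
    """Gray-level co-occurrence probability matrix at one displacement.

    The displacement follows the scikit-image convention: the pair partner of
    pixel (r, c) sits at (r + round(d sin a), c + round(d cos a)).  Pairs with
    a partner outside the image are skipped; the matrix is symmetrized (add
    transpose) and normalized to sum 1 when configured.
    """
    cfg = cfg or GLCMConfig()
    q = quantize(img, cfg.levels)
    dr = int(round(distance * np.sin(np.deg2rad(angle_deg))))
    dc = int(round(distance * np.cos(np.deg2rad(angle_deg))))
    if abs(dr) >= img.shape[0] or abs(dc) >= img.shape[1]:
        raise InputError(
            f"image shape {img.shape} smaller than displacement ({dr}, {dc})"
        )
    P = graycomatrix(
        q, distances=[distance], angles=[np.deg2rad(angle_deg)],
        levels=cfg.levels, symmetric=cfg.symmetric, normed=cfg.normalize,
    )[:, :, 0, 0]
    return P.astype(np.float64)


class HaralickStats(NamedTuple):
    contrast: float
    energy: float
    entropy: float
    correlation: float


def glcm_stats(P: np.ndarray) -> HaralickStats:
    """The four Haralick statistics of a normalized co-occurrence matrix.

    contrast = sum (i-j)^2 P_ij; energy = sum P_ij^2;
    entropy = -sum P_ij log2 P_ij (0 log 0 = 0);
    correlation = sum (i - mu_i)(j - mu_j) P_ij / (sigma_i sigma_j), defined
    as 1 when either marginal is degenerate (constant image).
    """
    P = np.asarray(P, dtype=np.float64)
    if abs(P.sum() - 1.0) > 1e-8:
        raise ValidationError("GLCM must be normalized (sum to 1)")
    n = P.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    contrast = float(((i - j) ** 2 * P).sum())
    energy = float((P**2).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(px @ np.arange(n))
    mu_y = float(py @ np.arange(n))
    var_x = float(px @ (np.arange(n) - mu_x) ** 2)
    var_y = float(py @ (np.arange(n) - mu_y) ** 2)
    if var_x <= 0 or var_y <= 0:
        correlation = 1.0
    else:
        correlation = float(
            (((i - mu_x) * (j - mu_y) * P).sum()) / np.sqrt(var_x * var_y)
        )
    return HaralickStats(contrast, energy, entropy, correlation)


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

# discrete 8-neighborhood offsets (row, col), counter-clockwise from east
_LBP_OFFSETS = (
    (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1),
)


def _uniform_lut() -> np.ndarray:
    """code -> bin: uniform patterns (<= 2 circular 0/1 transitions) map to
    their popcount (bins 0..8); everything else to bin 9."""
    lut = np.empty(256, dtype=np.int64)
    for code in range(256):
        bits = [(code >> k) & 1 for k in range(8)]
        transitions = sum(bits[k] != bits[(k + 1) % 8] for k in range(8))
        lut[code] = sum(bits) if transitions <= 2 else 9
    return lut


_LBP_LUT = _uniform_lut()


def lbp_codes(img: np.ndarray) -> np.ndarray:
    """8-bit LBP code per interior pixel (neighbor >= center sets the bit)."""
    img = validate_gray(img, min_size=3)
    center = img[1:-1, 1:-1].astype(np.int16)
    codes = np.zeros(center.shape, dtype=np.int64)
    for k, (dr, dc) in enumerate(_LBP_OFFSETS):
        neighbor = img[1 + dr : img.shape[0] - 1 + dr,
                       1 + dc : img.shape[1] - 1 + dc].astype(np.int16)
        codes |= (neighbor >= center).astype(np.int64) << k
    return codes


def lbp_histogram(img: np.ndarray) -> np.ndarray:
    """Normalized 10-bin uniform-LBP histogram (sums to 1)."""
    bins = _LBP_LUT[lbp_codes(img)]
    hist = np.bincount(bins.ravel(), minlength=10).astype(np.float64)
    return hist / hist.sum()


# ---------------------------------------------------------------------------
# Gabor
# ---------------------------------------------------------------------------

def gabor_kernel(size: int, frequency: float, theta_deg: float,
                 sigma: float = 2.0, psi: float = 0.0,
                 gamma_aspect: float = 1.0, zero_dc: bool = True) -> np.ndarray:
    """Real (cosine) Gabor kernel on a size x size grid.

    g(x, y) = exp(-(x'^2 + gamma^2 y'^2) / (2 sigma^2)) cos(2 pi f x' + psi)
    with (x', y') the theta-rotated coordinates about the kernel center.
    ``zero_dc`` subtracts the mean so constant regions give zero response.
    """
    if size % 2 == 0:
        raise ConfigError("Gabor kernel side must be odd")
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(np.float64)
    th = np.deg2rad(theta_deg)
    xr = x * np.cos(th) + y * np.sin(th)
    yr = -x * np.sin(th) + y * np.cos(th)
    k = np.exp(-(xr**2 + (gamma_aspect * yr) ** 2) / (2.0 * sigma**2)) * np.cos(
        2.0 * np.pi * frequency * xr + psi
    )
    if zero_dc:
        k -= k.mean()
    return k


def gabor_features(img: np.ndarray, cfg: GaborBankConfig | None = None) -> np.ndarray:
    """Mean and std of |response| for every kernel of the bank (16 values)."""
    cfg = cfg or GaborBankConfig()
    img = validate_gray(img, min_size=cfg.kernel_size)
    data = img.astype(np.float64) / 255.0
    out = []
    for f in cfg.frequencies:
        for theta in cfg.orientations_deg:
            k = gabor_kernel(cfg.kernel_size, f, theta, cfg.sigma,
                             cfg.phase_offset, cfg.aspect_ratio)
            resp = np.abs(ndimage.convolve(data, k, mode="reflect"))
            out.extend([float(resp.mean()), float(resp.std())])
    return np.array(out)


# ---------------------------------------------------------------------------
# assembly and standardization
# ---------------------------------------------------------------------------

def extract_features(
    img: np.ndarray,
    glcm_cfg: GLCMConfig | None = None,
    gabor_cfg: GaborBankConfig | None = None,
    lbp_on_gabor: bool = False,
) -> np.ndarray:
    """The full 58-value feature vector of one (preprocessed, ROI-cropped)
    cell image.

    ``lbp_on_gabor`` computes the LBP histogram on the summed absolute Gabor
    response (rescaled to 8 bit) instead of the raw ROI.
    """
    glcm_cfg = glcm_cfg or GLCMConfig()
    gabor_cfg = gabor_cfg or GaborBankConfig()
    values: list[float] = []
    for d in glcm_cfg.distances:
        for a in glcm_cfg.angles_deg:
            values.extend(glcm_stats(glcm(img, d, a, glcm_cfg)))
    if lbp_on_gabor:
        data = img.astype(np.float64) / 255.0
        total = np.zeros_like(data)
        for f in gabor_cfg.frequencies:
            for theta in gabor_cfg.orientations_deg:
                k = gabor_kernel(gabor_cfg.kernel_size, f, theta, gabor_cfg.sigma,
                                 gabor_cfg.phase_offset, gabor_cfg.aspect_ratio)
                total += np.abs(ndimage.convolve(data, k, mode="reflect"))
        hi = total.max()
        lbp_img = np.clip(np.rint(total / hi * 255.0) if hi > 0 else total, 0, 255
                          ).astype(np.uint8)
        values.extend(lbp_histogram(lbp_img))
    else:
        values.extend(lbp_histogram(img))
    values.extend(gabor_features(img, gabor_cfg))
    vec = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(vec)):
        raise ValidationError("non-finite feature value")
    return vec


@dataclass
class FeatureTransform:
    """Train-set z-scoring with optional variance-ranked pre-selection.

    ``select_idx`` (applied first) keeps the top-k raw features by variance;
    ``kept_idx`` then drops zero-variance features among the selected ones.
    Stored on the classifier so test-time vectors get the identical mapping.
    """

    mean: np.ndarray
    scale: np.ndarray
    kept_idx: np.ndarray
    select_idx: np.ndarray | None = None

    def apply(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if self.select_idx is not None:
            X = X[:, self.select_idx]
        return (X[:, self.kept_idx] - self.mean) / self.scale

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "kept_idx": self.kept_idx.tolist(),
            "select_idx": None if self.select_idx is None else self.select_idx.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureTransform":
        return cls(
            mean=np.asarray(d["mean"], dtype=np.float64),
            scale=np.asarray(d["scale"], dtype=np.float64),
            kept_idx=np.asarray(d["kept_idx"], dtype=np.int64),
            select_idx=(None if d.get("select_idx") is None
                        else np.asarray(d["select_idx"], dtype=np.int64)),
        )


def standardize_features(X: np.ndarray, top_k: int | None = None
                         ) -> tuple[FeatureTransform, np.ndarray]:
    """Fit per-feature z-scoring on training vectors.

    Zero-variance features are dropped (their indices recorded).  With
    ``top_k``, only the k highest-variance raw features are retained before
    standardization.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if len(X) < 2:
        raise ValidationError("standardization needs at least 2 training vectors")
    select_idx = None
    if top_k is not None and top_k < X.shape[1]:
        var = X.var(axis=0)
        select_idx = np.sort(np.argsort(-var, kind="stable")[:top_k])
        X = X[:, select_idx]
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 1e-12)
    tf = FeatureTransform(
        mean=X[:, kept].mean(axis=0), scale=sd[kept], kept_idx=kept,
        select_idx=select_idx,
    )
    # X is already selection-applied here; z-score directly
    return tf, (X[:, kept] - tf.mean) / tf.scale
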