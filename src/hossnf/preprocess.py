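"""Noise reduction and enhancement ahead of segmentation.

Three steps, each individually exposed and jointly driven by
:class:`PreprocessConfig`: a median filter (impulse noise, edge-preserving
smoothing), wavelet shrinkage with the universal threshold (Gaussian noise),
and a min-max intensity normalization.  The default order is
median -> wavelet -> normalize but is configurable, since either smoothing
step can reasonably come first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import ndimage

from .exceptions import ConfigError
from .imgio import validate_gray


@dataclass(frozen=True)
class PreprocessConfig:
    median_kernel: int = 3
    wavelet_name: str = "db4"
    decomposition_levels: int = 2
    threshold_rule: str = "soft"
    threshold_scale: float = 1.0
    #: subset/order of {"median", "wavelet", "normalize"} to apply
    order: tuple[str, ...] = ("median", "wavelet", "normalize")

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ConfigError(f"median kernel must be odd and >= 1, got {self.median_kernel}")
        if self.decomposition_levels < 1:
            raise ConfigError("decomposition_levels must be >= 1")
        if self.threshold_rule not in ("soft", "hard"):
            raise ConfigError(f"threshold_rule must be soft or hard, got {self.threshold_rule!r}")
        unknown = set(self.order) - {"median", "wavelet", "normalize"}
        if unknown:
            raise ConfigError(f"unknown preprocessing steps {sorted(unknown)}")


def median_filter(img: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median of the kernel x kernel neighborhood, reflect-padded borders."""
    img = validate_gray(img)
    if kernel % 2 == 0 or kernel < 1:
        raise ConfigError(f"median kernel must be odd and >= 1, got {kernel}")
    if kernel == 1:
        return img.copy()
    return ndimage.median_filter(img, size=kernel, mode="reflect")


def wavelet_denoise(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Multilevel wavelet shrinkage.

    Detail coefficients at every level are thresholded with the universal
    threshold sigma_hat * sqrt(2 ln n), sigma_hat estimated from the median
    absolute deviation of the finest diagonal details (MAD / 0.6745), scaled
    by ``cfg.threshold_scale``.  Reconstruction is clipped to [0, 255] and
    rounded back to uint8.
    """
    cfg = cfg or PreprocessConfig()
    img = validate_gray(img)
    if min(img.shape) < 2 ** cfg.decomposition_levels:
        raise ConfigError(
            f"image shape {img.shape} too small for {cfg.decomposition_levels} wavelet levels"
        )
    data = img.astype(np.float64)
    coeffs = pywt.wavedec2(data, cfg.wavelet_name, level=cfg.decomposition_levels,
                           mode="symmetric")
    finest_diag = coeffs[-1][2]
    sigma_hat = np.median(np.abs(finest_diag)) / 0.6745
    thr = cfg.threshold_scale * sigma_hat * np.sqrt(2.0 * np.log(data.size))
    if thr <= 0:  # no estimated noise: shrinkage is a no-op
        return img.copy()
    shrunk = [coeffs[0]]
    for detail in coeffs[1:]:
        shrunk.append(tuple(pywt.threshold(d, thr, mode=cfg.threshold_rule)
                            for d in detail))
    rec = pywt.waverec2(shrunk, cfg.wavelet_name, mode="symmetric")
    rec = rec[: img.shape[0], : img.shape[1]]
    return np.clip(np.rint(rec), 0, 255).astype(np.uint8)


def normalize_intensity(img: np.ndarray) -> np.ndarray:
    """Min-max stretch to [0, 255]; a constant image maps to 0."""
    img = validate_gray(img)
    lo, hi = int(img.min()), int(img.max())
    if hi == lo:
        return np.zeros_like(img)
    stretched = (img.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(stretched), 0, 255).astype(np.uint8)


def preprocess_image(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Apply the configured steps in the configured order."""
    cfg = cfg or PreprocessConfig()
    out = img
    for step in cfg.order:
        if step == "median":
            out = median_filter(out, cfg.median_kernel)
        elif step == "wavelet":
            out = wavelet_denoise(out, cfg)
        elif step == "normalize":
            out = normalize_intensity(out)
    return out
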