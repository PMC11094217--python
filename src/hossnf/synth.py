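"""Synthetic single-cell Pap-smear phantoms with ground-truth masks.

Each phantom is one cell on a bright background: an elliptical cytoplasm and a
darker elliptical nucleus fully contained in it (hematoxylin-stained nuclei
are the darkest structure in a Pap smear).  Class identity is encoded the way
cytologists grade dysplasia: the nucleus-to-cytoplasm area ratio and the
chromatin texture both increase with severity.  Texture is a seeded sum of
low-frequency sinusoids — enough to give the GLCM/LBP/Gabor features a
class-dependent signal without modeling real chromatin.

The generator exists so the whole pipeline is buildable and testable without
any external dataset; its per-class parameters are package choices, not
measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgio
from .exceptions import ConfigError, ValidationError
from .imgio import CLASS_NAMES, MANIFEST_COLUMNS, DatasetManifest

#: Severity ordering used for the monotone nucleus-size / texture ramps.
DYSPLASIA_ORDER: tuple[str, ...] = (
    "normal_squamous",
    "intermediate_squamous",
    "normal_columnar",
    "low_grade_dysplasia",
    "moderate_dysplasia",
    "high_grade_dysplasia",
    "carcinoma_in_situ",
)

# label values in masks
BACKGROUND, CYTOPLASM, NUCLEUS = 0, 1, 2


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters for one rendered cell image."""

    class_label: str
    image_size: int = 64
    nucleus_radius_range: tuple[float, float] = (4.5, 5.5)
    cytoplasm_radius_range: tuple[float, float] = (22.0, 26.0)
    background_mean: float = 230.0
    cytoplasm_mean: float = 160.0
    nucleus_mean: float = 70.0
    texture_amplitude: float = 0.0
    noise_sigma: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_NAMES:
            raise ValidationError(f"unknown class label {self.class_label!r}")
        if not (self.nucleus_radius_range[1] < self.cytoplasm_radius_range[0]):
            raise ConfigError("nucleus radius must be smaller than cytoplasm radius")
        if not (self.background_mean > self.cytoplasm_mean > self.nucleus_mean):
            raise ConfigError("intensity means must satisfy background > cytoplasm > nucleus")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.cytoplasm_radius_range[1] >= self.image_size / 2 - 1:
            raise ConfigError("cytoplasm radius exceeds image bounds")


# Per-class (nucleus radius range, texture amplitude): the nucleus radius
# ramps strictly upward along DYSPLASIA_ORDER (rising N/C ratio) and texture
# amplitude rises with dysplasia grade.
CLASS_PARAMS: dict[str, tuple[tuple[float, float], float]] = {
    "normal_squamous": ((4.5, 5.5), 2.0),
    "intermediate_squamous": ((6.0, 7.0), 2.0),
    "normal_columnar": ((7.5, 8.5), 3.0),
    "low_grade_dysplasia": ((9.5, 10.5), 6.0),
    "moderate_dysplasia": ((11.5, 12.5), 8.0),
    "high_grade_dysplasia": ((13.5, 14.5), 10.0),
    "carcinoma_in_situ": ((16.0, 17.5), 12.0),
}


def default_spec(class_label: str, seed: int = 0, noise_sigma: float = 5.0,
                 texture_scale: float = 1.0) -> PhantomSpec:
    """The study-condition spec for one class.

    ``texture_scale`` multiplies the class texture amplitude (0 gives the
    exact-intensity noise-free phantom used by the oracle tests).
    """
    radii, amp = CLASS_PARAMS[class_label]
    return PhantomSpec(
        class_label=class_label,
        nucleus_radius_range=radii,
        texture_amplitude=amp * texture_scale,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def _ellipse_mask(size: int, center: tuple[float, float],
                  radii: tuple[float, float], angle: float) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    y = rows - center[0]
    x = cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = x * ca + y * sa
    v = -x * sa + y * ca
    return (u / radii[1]) ** 2 + (v / radii[0]) ** 2 <= 1.0


def _band_limited_texture(size: int, rng: np.random.Generator) -> np.ndarray:
    """Sum of three unit-amplitude low-frequency sinusoids with random
    direction and phase; averaged so the result stays within [-1, 1]."""
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    tex = np.zeros((size, size))
    for _ in range(3):
        period = rng.uniform(8.0, 24.0)
        theta = rng.uniform(0.0, np.pi)
        phase = rng.uniform(0.0, 2 * np.pi)
        fy, fx = np.sin(theta) / period, np.cos(theta) / period
        tex += np.sin(2 * np.pi * (fy * rows + fx * cols) + phase)
    return tex / 3.0


def render_cell(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom; returns ``(image, label_mask)``.

    Deterministic for a fixed spec (including its seed).  The mask uses
    labels {0: background, 1: cytoplasm, 2: nucleus} and the nucleus ellipse
    is constructed to lie strictly inside the cytoplasm ellipse.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    center = size / 2.0

    cy_radii = (rng.uniform(*spec.cytoplasm_radius_range),
                rng.uniform(*spec.cytoplasm_radius_range))
    cy_angle = rng.uniform(0.0, np.pi)
    nu_radii = (rng.uniform(*spec.nucleus_radius_range),
                rng.uniform(*spec.nucleus_radius_range))
    nu_angle = rng.uniform(0.0, np.pi)

    # nucleus center offset bounded so the nucleus stays inside the cytoplasm
    slack = min(cy_radii) - max(nu_radii) - 1.0
    max_off = max(0.0, min(3.0, slack))
    off_r = rng.uniform(0.0, max_off)
    off_t = rng.uniform(0.0, 2 * np.pi)
    nu_center = (center + off_r * np.sin(off_t), center + off_r * np.cos(off_t))

    cyto = _ellipse_mask(size, (center, center), cy_radii, cy_angle)
    nucleus = _ellipse_mask(size, nu_center, nu_radii, nu_angle) & cyto

    mask = np.zeros((size, size), dtype=np.uint8)
    mask[cyto] = CYTOPLASM
    mask[nucleus] = NUCLEUS

    img = np.full((size, size), spec.background_mean, dtype=float)
    img[cyto] = spec.cytoplasm_mean
    img[nucleus] = spec.nucleus_mean

    if spec.texture_amplitude > 0:
        tex = _band_limited_texture(size, rng)
        cell = mask > 0
        img[cell] += spec.texture_amplitude * tex[cell]
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, img.shape)

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, mask


def largest_remainder_split(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Apportion ``n`` items to (train, test, validation) by largest remainder,
    so the parts always sum exactly to ``n``."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"split fractions must sum to 1, got {fractions}")
    exact = np.asarray(fractions) * n
    base = np.floor(exact).astype(int)
    shortfall = n - int(base.sum())
    # distribute leftovers to the largest fractional parts; ties by position
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:shortfall]:
        base[i] += 1
    return tuple(int(b) for b in base)


def generate_dataset(
    n_per_class: int,
    out_dir: str | Path,
    seed: int = 0,
    split_fractions: tuple[float, float, float] = (0.7, 0.3, 0.0),
    noise_sigma: float = 5.0,
    texture_scale: float = 1.0,
    image_size: int = 64,
) -> DatasetManifest:
    """Render ``n_per_class`` phantoms per class, write images, masks and a
    manifest under ``out_dir``; deterministic given the seed.

    Layout: ``images/<class>_<idx>.png``, ``masks/<class>_<idx>.png``,
    ``manifest.csv``.  Per-class split sizes use largest-remainder rounding.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    n_tr, n_te, n_va = largest_remainder_split(n_per_class, split_fractions)
    splits = ["train"] * n_tr + ["test"] * n_te + ["validation"] * n_va

    rows: list[tuple[str, str, str]] = []
    for ci, label in enumerate(CLASS_NAMES):
        for k in range(n_per_class):
            img_seed = int(
                np.random.SeedSequence([seed, ci, k]).generate_state(1)[0] % (2**31)
            )
            spec = replace(
                default_spec(label, seed=img_seed, noise_sigma=noise_sigma,
                             texture_scale=texture_scale),
                image_size=image_size,
            )
            img, mask = render_cell(spec)
            name = f"{label}_{k:03d}.png"
            imgio.write_image(out_dir / "images" / name, img)
            imgio.write_image(out_dir / "masks" / name, mask)
            rows.append((f"images/{name}", label, splits[k]))

    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    manifest = DatasetManifest(records=df, root=out_dir)
    imgio.write_manifest(out_dir / "manifest.csv", manifest)
    return manifest


def gaussian_feature_clusters(
    n_train: int = 100,
    n_test: int = 50,
    n_features: int = 8,
    offset: float = 4.5,
    sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[str], np.ndarray, list[str]]:
    """Synthetic 7-class feature clusters for classifier-recovery checks.

    Class c's center sits at ``offset`` along feature axis c (orthogonal
    placement), giving every pair of centers distance offset * sqrt(2) —
    about 6.4 standard deviations at the defaults, so the Bayes error is
    negligible and a recovery check measures the trainer, not sampling luck.
    Samples cycle through the classes so per-class counts are balanced.
    Returns (X_train, y_train, X_test, y_test).
    """
    rng = np.random.default_rng(seed)
    centers = np.zeros((len(CLASS_NAMES), n_features))
    for c in range(len(CLASS_NAMES)):
        centers[c, c % n_features] = offset

    def draw(n: int) -> tuple[np.ndarray, list[str]]:
        X, y = [], []
        for i in range(n):
            c = i % len(CLASS_NAMES)
            X.append(centers[c] + rng.normal(0.0, sd, n_features))
            y.append(CLASS_NAMES[c])
        return np.asarray(X), y

    Xtr, ytr = draw(n_train)
    Xte, yte = draw(n_test)
    return Xtr, ytr, Xte, yte


def mask_path_for(manifest: DatasetManifest, image_path: str) -> Path | None:
    """Ground-truth mask location by the images/ -> masks/ convention, or
    None when no such file exists."""
    p = manifest.resolve(image_path)
    candidate = p.parent.parent / "masks" / p.name
    return candidate if candidate.exists() else None
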