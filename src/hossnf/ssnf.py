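"""Six-layer self-systematized neural fuzzy (SsNF) classifier.

The network is a TSK-style fuzzy system: layer 1 passes the crisp inputs
through; layer 2 evaluates Gaussian memberships mu = exp(-(x - d)^2 / s^2);
layer 3 conjoins them per rule by product, giving the firing strength
f_j = exp(-sum_m (x_m - d_jm)^2 / s_jm^2); layer 4 normalizes the firings
onto the simplex; layer 5 evaluates each rule's linear consequent
(k_j . x + b_j) per class, scaled by the normalized firing; layer 6 sums the
rule contributions per class.  The class scores are therefore a convex
combination of the rule consequents and classification is their argmax.

"Self-systematized" refers to structure learning: rules are seeded one per
class at the class-conditional feature means, then grown online whenever a
training sample fires every existing rule below a novelty threshold.
Parameter fitting is derivative-free: all rule centers, widths, consequent
weights and biases are flattened into one vector and handed to the
heap-based optimizer, with the structure-learning result seeding one search
agent so greedy acceptance can only improve on it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import heapopt
from .exceptions import ConfigError, SchemaError, ValidationError
from .heapopt import HOConfig
from .imgio import CLASS_NAMES
from .texture import FeatureTransform

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

# box bounds for the HBO parameter search, in standardized feature units
CENTER_BOUND = 3.0
WIDTH_BOUNDS = (0.1, 5.0)
WEIGHT_BOUND = 5.0


@dataclass
class FuzzyRule:
    centers: np.ndarray   # (n_inputs,) Gaussian means
    widths: np.ndarray    # (n_inputs,) Gaussian widths, > 0
    weights: np.ndarray   # (n_classes, n_inputs) consequent slopes
    biases: np.ndarray    # (n_classes,) consequent offsets (output MF centers)

    def __post_init__(self) -> None:
        if np.any(self.widths <= 0):
            raise ValidationError("rule widths must be positive")
        n = len(self.centers)
        if self.widths.shape != (n,) or self.weights.shape[1] != n \
                or self.weights.shape[0] != len(self.biases):
            raise ValidationError("inconsistent rule array shapes")


@dataclass
class SsNFModel:
    n_inputs: int
    class_names: tuple[str, ...]
    rules: list[FuzzyRule]
    transform: FeatureTransform | None = None
    default_widths: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        C = np.stack([r.centers for r in self.rules])
        W = np.stack([r.widths for r in self.rules])
        K = np.stack([r.weights for r in self.rules])
        B = np.stack([r.biases for r in self.rules])
        return C, W, K, B


@dataclass(frozen=True)
class TrainConfig:
    n_init_mf: int = 3
    f_min: float = 0.1
    budget: int = 2000            # HBO objective evaluations
    population_size: int = 20
    loss_name: str = "mse"
    feature_top_k: int | None = None
    #: optional ridge least-squares consequent initialization (TSK hybrid
    #: learning); off by default — with few samples per class the extra
    #: linear terms overfit and one-hot biases generalize better
    ls_consequents: bool = False
    ls_ridge: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.f_min < 1.0):
            raise ConfigError("f_min must lie in (0, 1)")
        if self.budget < 1:
            raise ConfigError("budget must be >= 1")
        if self.loss_name != "mse":
            raise ConfigError(f"unknown loss {self.loss_name!r}")


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

def mf_eval(mean: float, width: float, x: float) -> float:
    """Gaussian membership mu = exp(-(x - mean)^2 / width^2)."""
    return float(np.exp(-((x - mean) ** 2) / width**2))


def rule_firing(rule: FuzzyRule, x: np.ndarray) -> float:
    """Product of per-input memberships = exp(-sum (x-d)^2 / s^2)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != rule.centers.shape:
        raise ValidationError(f"input dim {x.shape} != rule dim {rule.centers.shape}")
    return float(np.exp(-np.sum(((x - rule.centers) / rule.widths) ** 2)))


def normalize_firings(f: np.ndarray) -> np.ndarray:
    """Project raw firings onto the simplex; an all-zero vector (numeric
    underflow) falls back to the uniform distribution with a warning."""
    f = np.asarray(f, dtype=np.float64)
    s = f.sum()
    if s <= 0:
        logger.warning("all rule firings underflowed to zero; using uniform weights")
        return np.full(len(f), 1.0 / len(f))
    return f / s


def _log_firings(model: SsNFModel, X: np.ndarray) -> np.ndarray:
    """(N, R) matrix of log firing strengths (-sum of squared z-scores)."""
    C, W, _, _ = model.stacked()
    z = (X[:, None, :] - C[None, :, :]) / W[None, :, :]
    return -(z**2).sum(axis=2)


def _normalized_firings_batch(model: SsNFModel, X: np.ndarray) -> np.ndarray:
    """Normalized firings computed in log space (shift by the row max), so
    deeply negative exponents cannot underflow the whole row."""
    logf = _log_firings(model, X)
    logf -= logf.max(axis=1, keepdims=True)
    f = np.exp(logf)
    return f / f.sum(axis=1, keepdims=True)


def consequent_output(rule: FuzzyRule, x: np.ndarray, f_norm: float) -> np.ndarray:
    """One rule's per-class contribution (k_c . x + b_c) * f_norm."""
    x = np.asarray(x, dtype=np.float64)
    return (rule.weights @ x + rule.biases) * f_norm


def forward_batch(model: SsNFModel, X: np.ndarray) -> np.ndarray:
    """(N, n_classes) class scores for already-transformed inputs."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_inputs:
        raise ValidationError(
            f"input dim {X.shape[1]} != model n_inputs {model.n_inputs}"
        )
    fbar = _normalized_firings_batch(model, X)          # (N, R)
    _, _, K, B = model.stacked()                        # K: (R, C, n), B: (R, C)
    cons = np.einsum("rcn,Nn->Nrc", K, X) + B[None]     # (N, R, C)
    return np.einsum("Nr,Nrc->Nc", fbar, cons)


def forward(model: SsNFModel, x: np.ndarray) -> np.ndarray:
    """Class score vector for one (already-transformed) input."""
    return forward_batch(model, x)[0]


def classify(model: SsNFModel, x: np.ndarray) -> str:
    """Label = argmax of scores; exact ties resolve to the lowest class
    index (logged)."""
    scores = forward(model, x)
    top = int(np.argmax(scores))
    if np.count_nonzero(scores == scores[top]) > 1:
        logger.info("tie between classes at scores %s; taking lowest index", scores)
    return model.class_names[top]


def classify_batch(model: SsNFModel, X: np.ndarray) -> list[str]:
    scores = forward_batch(model, X)
    return [model.class_names[int(i)] for i in np.argmax(scores, axis=1)]


# ---------------------------------------------------------------------------
# structure learning
# ---------------------------------------------------------------------------

def init_structure(X: np.ndarray, y: list[str], cfg: TrainConfig,
                   class_names: tuple[str, ...] = CLASS_NAMES) -> SsNFModel:
    """Initial rule base from the training data (already standardized).

    Per-input membership grids sit at ``n_init_mf`` pooled quantiles; the
    default rule width per input is the mean spacing between adjacent
    grid centers, scaled by sqrt(n_inputs) and floored at 0.1.  The sqrt
    scaling keeps the product firing exp(-sum_m z_m^2) of a typical
    same-cluster sample at O(1) regardless of dimensionality — without it
    every high-dimensional sample looks novel to the rule-growth check and
    the rule base degenerates to one rule per sample.  One rule per present
    class is centered at the class-conditional feature mean with a one-hot
    consequent bias.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    y = list(y)
    if len(np.unique(X, axis=0)) < cfg.n_init_mf:
        raise ValidationError(
            f"need >= {cfg.n_init_mf} distinct training points"
        )
    n = X.shape[1]
    qs = (np.arange(cfg.n_init_mf) + 0.5) / cfg.n_init_mf
    grid = np.quantile(X, qs, axis=0)                    # (n_mf, n)
    spacing = np.diff(grid, axis=0)
    mean_gap = spacing.mean(axis=0) if len(spacing) else np.zeros(n)
    default_widths = np.maximum(mean_gap * np.sqrt(n), 0.1)

    present = [c for c in class_names if c in set(y)]
    if not present:
        raise ValidationError("no known class labels in training data")
    y_arr = np.asarray(y)
    rules = []
    n_classes = len(class_names)
    for c in present:
        sel = X[y_arr == c]
        bias = np.zeros(n_classes)
        bias[class_names.index(c)] = 1.0
        rules.append(FuzzyRule(
            centers=sel.mean(axis=0),
            widths=default_widths.copy(),
            weights=np.zeros((n_classes, n)),
            biases=bias,
        ))
    return SsNFModel(n_inputs=n, class_names=tuple(class_names), rules=rules,
                     default_widths=default_widths)


def self_systematize(model: SsNFModel, x: np.ndarray, label: str,
                     f_min: float) -> SsNFModel:
    """Grow one rule at ``x`` when no existing rule fires above ``f_min``."""
    x = np.asarray(x, dtype=np.float64)
    max_logf = _log_firings(model, x[None, :])[0].max()
    if max_logf >= np.log(f_min):
        return model
    widths = (model.default_widths.copy() if model.default_widths is not None
              else np.full(model.n_inputs, 1.0))
    bias = np.zeros(model.n_classes)
    bias[model.class_names.index(label)] = 1.0
    model.rules.append(FuzzyRule(
        centers=x.copy(), widths=widths,
        weights=np.zeros((model.n_classes, model.n_inputs)), biases=bias,
    ))
    return model


# ---------------------------------------------------------------------------
# loss and parameter fitting
# ---------------------------------------------------------------------------

def one_hot(y: list[str], class_names: tuple[str, ...]) -> np.ndarray:
    idx = np.array([class_names.index(c) for c in y])
    Y = np.zeros((len(y), len(class_names)))
    Y[np.arange(len(y)), idx] = 1.0
    return Y


def loss(model: SsNFModel, X: np.ndarray, y: list[str]) -> float:
    """Mean squared error between raw class scores and one-hot targets,
    averaged over samples and classes."""
    if len(X) == 0:
        raise ValidationError("empty dataset")
    scores = forward_batch(model, X)
    Y = one_hot(y, model.class_names)
    return float(((scores - Y) ** 2).mean())


def _fit_consequents_ls(model: SsNFModel, X: np.ndarray, y: list[str],
                        ridge: float = 1e-3) -> None:
    """Hybrid-learning step: with antecedents fixed, the class scores are
    linear in the consequent parameters, so fit them by ridge-regularized
    least squares against the one-hot targets (the classic TSK estimator).
    Results are clipped into the HBO search box."""
    fbar = _normalized_firings_batch(model, X)                 # (N, R)
    Xa = np.hstack([X, np.ones((len(X), 1))])                  # (N, n+1)
    A = (fbar[:, :, None] * Xa[:, None, :]).reshape(len(X), -1)
    Y = one_hot(y, model.class_names)
    G = A.T @ A + ridge * np.eye(A.shape[1])
    coef = np.linalg.solve(G, A.T @ Y)                         # (R(n+1), C)
    coef = np.clip(coef, -WEIGHT_BOUND, WEIGHT_BOUND)
    n = model.n_inputs
    for j, rule in enumerate(model.rules):
        block = coef[j * (n + 1) : (j + 1) * (n + 1)]          # (n+1, C)
        rule.weights = block[:n].T.copy()
        rule.biases = block[n].copy()


def _pack(model: SsNFModel) -> np.ndarray:
    parts = []
    for r in model.rules:
        parts.extend([r.centers, r.widths, r.weights.ravel(), r.biases])
    return np.concatenate(parts)


def _unpack(vec: np.ndarray, template: SsNFModel) -> SsNFModel:
    n, C = template.n_inputs, template.n_classes
    per_rule = 2 * n + C * n + C
    rules = []
    for j in range(len(template.rules)):
        chunk = vec[j * per_rule : (j + 1) * per_rule]
        rules.append(FuzzyRule(
            centers=chunk[:n].copy(),
            widths=chunk[n : 2 * n].copy(),
            weights=chunk[2 * n : 2 * n + C * n].reshape(C, n).copy(),
            biases=chunk[2 * n + C * n :].copy(),
        ))
    return SsNFModel(n_inputs=n, class_names=template.class_names, rules=rules,
                     transform=template.transform,
                     default_widths=template.default_widths)


def _bounds(template: SsNFModel) -> tuple[np.ndarray, np.ndarray]:
    n, C = template.n_inputs, template.n_classes
    lo_rule = np.concatenate([
        np.full(n, -CENTER_BOUND), np.full(n, WIDTH_BOUNDS[0]),
        np.full(C * n + C, -WEIGHT_BOUND),
    ])
    hi_rule = np.concatenate([
        np.full(n, CENTER_BOUND), np.full(n, WIDTH_BOUNDS[1]),
        np.full(C * n + C, WEIGHT_BOUND),
    ])
    R = len(template.rules)
    return np.tile(lo_rule, R), np.tile(hi_rule, R)


def train(X: np.ndarray, y: list[str], cfg: TrainConfig | None = None,
          class_names: tuple[str, ...] = CLASS_NAMES,
          transform: FeatureTransform | None = None) -> SsNFModel:
    """Structure learning plus HBO parameter fitting.

    ``X`` must already be standardized (the fitted transform may be passed
    for storage on the model).  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if len(set(y)) < 2:
        raise ValidationError("training needs at least 2 classes present")

    model = init_structure(X, y, cfg, class_names)
    model.transform = transform
    for xi, yi in zip(X, y):
        self_systematize(model, xi, yi, cfg.f_min)
    if cfg.ls_consequents:
        _fit_consequents_ls(model, X, y, ridge=cfg.ls_ridge)

    x0 = _pack(model)
    lo, hi = _bounds(model)
    iters = max(1, cfg.budget // cfg.population_size)
    ho_cfg = HOConfig(
        dimensions=len(x0), lower_bounds=lo, upper_bounds=hi,
        population_size=cfg.population_size, max_iterations=iters,
        seed=cfg.seed, initial_positions=x0[None, :],
    )

    def objective(vec: np.ndarray) -> float:
        return loss(_unpack(vec, model), X, y)

    res = heapopt.optimize(objective, ho_cfg)
    fitted = _unpack(res.best_position, model)
    logger.info("SsNF training: %d rules, final loss %.6f (%d evals)",
                len(fitted.rules), res.best_fitness, res.n_evals)
    return fitted


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: SsNFModel, path: str | Path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "n_inputs": model.n_inputs,
        "class_names": list(model.class_names),
        "transform": None if model.transform is None else model.transform.to_dict(),
        "default_widths": (None if model.default_widths is None
                           else model.default_widths.tolist()),
        "rules": [
            {
                "centers": r.centers.tolist(),
                "widths": r.widths.tolist(),
                "weights": r.weights.tolist(),
                "biases": r.biases.tolist(),
            }
            for r in model.rules
        ],
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> SsNFModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported model schema {doc.get('schema_version')!r}; "
            f"expected {SCHEMA_VERSION}"
        )
    rules = [
        FuzzyRule(
            centers=np.asarray(r["centers"], dtype=np.float64),
            widths=np.asarray(r["widths"], dtype=np.float64),
            weights=np.asarray(r["weights"], dtype=np.float64),
            biases=np.asarray(r["biases"], dtype=np.float64),
        )
        for r in doc["rules"]
    ]
    return SsNFModel(
        n_inputs=int(doc["n_inputs"]),
        class_names=tuple(doc["class_names"]),
        rules=rules,
        transform=(None if doc["transform"] is None
                   else FeatureTransform.from_dict(doc["transform"])),
        default_widths=(None if doc["default_widths"] is None
                        else np.asarray(doc["default_widths"], dtype=np.float64)),
    )
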