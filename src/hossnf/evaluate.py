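"""Confusion-matrix metrics and end-to-end pipeline orchestration.

Reporting follows the screening convention: the four abnormal classes
(low/moderate/high-grade dysplasia, carcinoma in situ) are the positive
group and the three normal morphologies the negative group, reduced to a
2x2 confusion table with specificity, sensitivity/recall, accuracy,
precision/PPV and NPV.  The full 7x7 confusion matrix, per-class
one-vs-rest tables and macro averages are always reported alongside.
Metrics with a zero denominator surface as None (never silently 0).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import imgio, preprocess, segment, ssnf, synth, texture
from .exceptions import InputError, ValidationError
from .heapopt import HOConfig
from .imgio import ABNORMAL_CLASSES, CLASS_NAMES, DatasetManifest

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(y_true: list[str], y_pred: list[str],
              positive: frozenset[str] = ABNORMAL_CLASSES) -> ConfusionCounts:
    """Binary reduction of label sequences against a positive class set."""
    if len(y_true) != len(y_pred):
        raise InputError(f"label length mismatch: {len(y_true)} vs {len(y_pred)}")
    if not y_true:
        raise InputError("empty label sequences")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        t_pos = t in positive
        p_pos = p in positive
        if t_pos and p_pos:
            tp += 1
        elif not t_pos and not p_pos:
            tn += 1
        elif not t_pos and p_pos:
            fp += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def specificity(c: ConfusionCounts) -> float | None:
    return _ratio(c.tn, c.tn + c.fp)


def sensitivity(c: ConfusionCounts) -> float | None:
    return _ratio(c.tp, c.tp + c.fn)


def accuracy(c: ConfusionCounts) -> float | None:
    return _ratio(c.tp + c.tn, c.total)


def precision(c: ConfusionCounts) -> float | None:
    return _ratio(c.tp, c.tp + c.fp)


def npv(c: ConfusionCounts) -> float | None:
    return _ratio(c.tn, c.tn + c.fn)


def binary_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    return {
        "specificity": specificity(c),
        "sensitivity": sensitivity(c),
        "accuracy": accuracy(c),
        "precision": precision(c),
        "npv": npv(c),
    }


@dataclass
class MetricsReport:
    binary: dict[str, float | None]
    binary_counts: ConfusionCounts
    confusion_matrix: np.ndarray            # 7x7, rows = true class
    per_class: dict[str, dict[str, float | None]]
    macro: dict[str, float | None]
    class_names: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "binary": self.binary,
            "binary_counts": dataclasses.asdict(self.binary_counts),
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_class": self.per_class,
            "macro": self.macro,
            "class_names": list(self.class_names),
        }


def metrics_report(y_true: list[str], y_pred: list[str],
                   class_names: tuple[str, ...] = CLASS_NAMES) -> MetricsReport:
    """Binary normal-vs-abnormal metrics plus the full multiclass view."""
    cm = np.zeros((len(class_names), len(class_names)), dtype=int)
    idx = {c: i for i, c in enumerate(class_names)}
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    per_class: dict[str, dict[str, float | None]] = {}
    for c in class_names:
        counts = confusion(y_true, y_pred, positive=frozenset({c}))
        per_class[c] = binary_metrics(counts)
    macro: dict[str, float | None] = {}
    for m in ("specificity", "sensitivity", "accuracy", "precision", "npv"):
        vals = [per_class[c][m] for c in class_names if per_class[c][m] is not None]
        macro[m] = float(np.mean(vals)) if vals else None
    bc = confusion(y_true, y_pred)
    return MetricsReport(
        binary=binary_metrics(bc), binary_counts=bc, confusion_matrix=cm,
        per_class=per_class, macro=macro, class_names=tuple(class_names),
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data": {"manifest": None},
    "preprocess": {
        "median_kernel": 3,
        "wavelet_name": "db4",
        "decomposition_levels": 2,
        "threshold_rule": "soft",
        "threshold_scale": 1.0,
        "order": ["median", "wavelet", "normalize"],
    },
    "segment": {
        "n_thresholds": 2,
        "objective": "otsu",
        "restarts": 2,
        "roi_margin": 2,
        "ho": {"population_size": 20, "max_iterations": 50},
    },
    "features": {"lbp_on_gabor": False},
    "ssnf": {
        "n_init_mf": 3,
        "f_min": 0.1,
        "budget": 2000,
        "population_size": 20,
        "feature_top_k": None,
    },
}


def _merged(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merged(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict: str | Path | dict) -> dict:
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        p = Path(path_or_dict)
        if not p.exists():
            raise InputError(f"config file not found: {p}")
        user = yaml.safe_load(p.read_text()) or {}
    return _merged(DEFAULT_CONFIG, user)


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def _process_record(img_path: Path, mask_path: Path | None, cfg: dict,
                    seed: int) -> tuple[np.ndarray, float | None, tuple[int, ...]]:
    """Preprocess, segment and featurize one image.

    Returns (feature vector, nucleus Dice vs ground truth or None, thresholds).
    """
    img = imgio.read_image(img_path)
    pre_cfg = preprocess.PreprocessConfig(
        median_kernel=cfg["preprocess"]["median_kernel"],
        wavelet_name=cfg["preprocess"]["wavelet_name"],
        decomposition_levels=cfg["preprocess"]["decomposition_levels"],
        threshold_rule=cfg["preprocess"]["threshold_rule"],
        threshold_scale=cfg["preprocess"]["threshold_scale"],
        order=tuple(cfg["preprocess"]["order"]),
    )
    pre = preprocess.preprocess_image(img, pre_cfg)

    seg = cfg["segment"]
    ho_cfg = HOConfig(
        dimensions=seg["n_thresholds"], lower_bounds=1.0, upper_bounds=254.0,
        population_size=seg["ho"]["population_size"],
        max_iterations=seg["ho"]["max_iterations"], seed=seed,
    )
    ts, _ = segment.ho_threshold_search(
        pre, seg["n_thresholds"], cfg=ho_cfg, objective=seg["objective"],
        restarts=seg["restarts"],
    )
    pred_mask = segment.apply_thresholds(pre, ts)

    dice_nucleus = None
    if mask_path is not None:
        truth = imgio.read_image(mask_path)
        dice_nucleus = segment.overlap_metrics(pred_mask, truth).dice[synth.NUCLEUS]

    roi = segment.extract_roi(pre, pred_mask, margin=seg["roi_margin"])
    vec = texture.extract_features(roi, lbp_on_gabor=cfg["features"]["lbp_on_gabor"])
    return vec, dice_nucleus, ts.thresholds


def run_pipeline(config: str | Path | dict, run_dir: str | Path) -> dict:
    """Execute preprocess -> segmentation -> features -> train -> classify ->
    metrics over a manifest's train/test splits.

    Writes features.csv, model.json, predictions.csv, metrics.json and the
    resolved config into ``run_dir``; fully deterministic given the config
    seed.  Returns the metrics document (also stored as metrics.json),
    which includes the mean nucleus Dice over each split when ground-truth
    masks are present.
    """
    cfg = load_config(config)
    seed = int(cfg["seed"])
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    manifest_path = cfg["data"].get("manifest")
    if not manifest_path or not Path(manifest_path).exists():
        raise InputError(f"manifest not found: {manifest_path!r}")
    manifest = imgio.load_manifest(manifest_path)

    stage_t0 = time.perf_counter()
    rows = manifest.records.reset_index(drop=True)
    feats: list[np.ndarray] = []
    dices: list[float | None] = []
    thresholds: list[tuple[int, ...]] = []
    for i, rec in rows.iterrows():
        vec, dice, ts = _process_record(
            manifest.resolve(rec["image_path"]),
            synth.mask_path_for(manifest, rec["image_path"]),
            cfg, seed=_sub_seed(seed, 1, i),
        )
        feats.append(vec)
        dices.append(dice)
        thresholds.append(ts)
    X = np.vstack(feats)
    logger.info("segmentation+features for %d images in %.1fs", len(rows),
                time.perf_counter() - stage_t0)

    feat_df = pd.DataFrame(X, columns=list(texture.FEATURE_NAMES))
    feat_df.insert(0, "image_path", rows["image_path"])
    feat_df["nucleus_dice"] = dices
    feat_df.to_csv(run_dir / "features.csv", index=False)

    train_idx = rows.index[rows["split"] == "train"].to_numpy()
    test_idx = rows.index[rows["split"] == "test"].to_numpy()
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValidationError("manifest needs non-empty train and test splits")

    ncfg = cfg["ssnf"]
    tf, Xtr = texture.standardize_features(
        X[train_idx], top_k=ncfg["feature_top_k"]
    )
    stage_t0 = time.perf_counter()
    model = ssnf.train(
        Xtr, list(rows.loc[train_idx, "class_label"]),
        ssnf.TrainConfig(
            n_init_mf=ncfg["n_init_mf"], f_min=ncfg["f_min"],
            budget=ncfg["budget"], population_size=ncfg["population_size"],
            feature_top_k=None, seed=_sub_seed(seed, 2),
        ),
        transform=tf,
    )
    logger.info("SsNF training in %.1fs", time.perf_counter() - stage_t0)
    ssnf.save_model(model, run_dir / "model.json")

    y_true = list(rows.loc[test_idx, "class_label"])
    y_pred = ssnf.classify_batch(model, tf.apply(X[test_idx]))
    report = metrics_report(y_true, y_pred)

    pred_df = pd.DataFrame({
        "image_path": rows.loc[test_idx, "image_path"],
        "true_label": y_true,
        "predicted_label": y_pred,
    })
    pred_df.to_csv(run_dir / "predictions.csv", index=False)

    def _mean_dice(idx: np.ndarray) -> float | None:
        vals = [dices[i] for i in idx if dices[i] is not None]
        return float(np.mean(vals)) if vals else None

    doc = report.to_dict()
    doc["seed"] = seed
    doc["n_train"] = int(len(train_idx))
    doc["n_test"] = int(len(test_idx))
    doc["mean_nucleus_dice_train"] = _mean_dice(train_idx)
    doc["mean_nucleus_dice_test"] = _mean_dice(test_idx)
    (run_dir / "metrics.json").write_text(json.dumps(doc, indent=1))
    (run_dir / "config.yaml").write_text(yaml.safe_dump(cfg))
    return doc
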