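"""Confusion-matrix metrics and the two evaluation harnesses.

Metrics follow the usual clinical definitions with malignant as the
positive class: accuracy (Pt+Nt)/total, sensitivity Pt/(Pt+Nf) and
specificity Nt/(Nt+Pf), reported in percent. Degenerate denominators are
flagged as undefined (NaN), never coerced to 0 or 100.

The harnesses run the full pipeline — preprocess, extract features, train
the CNN, tune its head with the falcon finch optimizer, predict the
held-out partition — either over stratified k folds or over a single
training-percentage split.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from falconfinch import cnn as _cnn
from falconfinch import ffo as _ffo
from falconfinch.features import denoise as _denoise, extract, standardize
from falconfinch.synthetic_data import BENIGN, MALIGNANT, LabeledImage

POSITIVE_LABEL = MALIGNANT  # clinical convention


# ---------------------------------------------------------------------------
# metrics


@dataclass
class ConfusionCounts:
    """Pt/Nt/Pf/Nf counts (positive = malignant)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[int], y_pred: Sequence[int]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true).astype(int)
        yp = np.asarray(y_pred).astype(int)
        if yt.shape != yp.shape:
            raise ValueError("prediction/truth length mismatch")
        return cls(
            tp=int(np.sum((yt == 1) & (yp == 1))),
            tn=int(np.sum((yt == 0) & (yp == 0))),
            fp=int(np.sum((yt == 0) & (yp == 1))),
            fn=int(np.sum((yt == 1) & (yp == 0))),
        )


@dataclass
class Metrics:
    accuracy: float  # percent
    sensitivity: float  # percent, NaN when undefined
    specificity: float  # percent, NaN when undefined
    sensitivity_defined: bool = True
    specificity_defined: bool = True

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.accuracy, self.sensitivity, self.specificity)


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy / sensitivity / specificity in percent; NaN when undefined."""
    if c.total == 0:
        raise ValueError("no evaluated samples")
    acc = 100.0 * (c.tp + c.tn) / c.total
    sen_def = (c.tp + c.fn) > 0
    spe_def = (c.tn + c.fp) > 0
    sen = 100.0 * c.tp / (c.tp + c.fn) if sen_def else math.nan
    spe = 100.0 * c.tn / (c.tn + c.fp) if spe_def else math.nan
    return Metrics(acc, sen, spe, sen_def, spe_def)


# ---------------------------------------------------------------------------
# splits


def kfold_split(
    n: int, k: int, labels: Sequence, seed: int = 0
) -> list[np.ndarray]:
    """Stratified disjoint folds covering 0..n-1 (test-index lists).

    Each fold's class ratio is within one sample of the global ratio.
    ``k == n`` degenerates to seeded leave-one-out (stratification vacuous).
    """
    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels length must equal n")
    if not 2 <= k <= n:
        raise ValueError("need 2 <= k <= n")
    if k == n:
        order = np.random.default_rng(seed).permutation(n)
        return [np.array([i]) for i in order]
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer samples than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(n), labels)]


# ---------------------------------------------------------------------------
# harness


@dataclass
class PipelineConfig:
    """Desk-scale defaults for the end-to-end pipeline."""

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-4
    denoise: bool = True
    denoise_strength: float = 10.0 / 255.0
    tune_fraction: float = 0.25  # share of the training part held out for ffo_tune
    ffo_population: int = 20
    ffo_iterations: int = 30
    backbone_seed: int = 13
    seed: int = 0

    def echo(self) -> dict:
        return asdict(self)


@dataclass
class EvaluationReport:
    mode: str  # "kfold" or "split"
    parameter: float  # k or train percentage
    folds: list[ConfusionCounts]
    fold_metrics: list[Metrics]
    mean_accuracy: float
    mean_sensitivity: float
    mean_specificity: float
    seed: int
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode,
            "parameter": self.parameter,
            "folds": [asdict(c) for c in self.folds],
            "fold_metrics": [asdict(m) for m in self.fold_metrics],
            "mean_accuracy": round(self.mean_accuracy, 2),
            "mean_sensitivity": round(self.mean_sensitivity, 2),
            "mean_specificity": round(self.mean_specificity, 2),
            "seed": self.seed,
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path) -> None:
        rows = []
        for i, m in enumerate(self.fold_metrics):
            rows.append(
                {
                    "fold": i + 1,
                    "accuracy": round(m.accuracy, 2),
                    "sensitivity": round(m.sensitivity, 2),
                    "specificity": round(m.specificity, 2),
                }
            )
        rows.append(
            {
                "fold": "mean",
                "accuracy": round(self.mean_accuracy, 2),
                "sensitivity": round(self.mean_sensitivity, 2),
                "specificity": round(self.mean_specificity, 2),
            }
        )
        pd.DataFrame(rows).to_csv(path, index=False)


def prepare_planes(
    images: Sequence[LabeledImage],
    config: Optional[PipelineConfig] = None,
    backbone=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess and featurize: returns raw 109-d feature matrix and 0/1 labels."""
    from falconfinch.features import RandomProjectionBackbone

    config = config or PipelineConfig()
    if backbone is None:
        backbone = RandomProjectionBackbone(seed=config.backbone_seed)
    feats, labels = [], []
    for li in images:
        raster = li.raster
        if config.denoise:
            raster = _denoise(raster, strength=config.denoise_strength)
        fv = extract(standardize(raster), backbone)
        feats.append(fv.values)
        labels.append(1 if li.label == POSITIVE_LABEL else 0)
    return np.asarray(feats), np.asarray(labels, dtype=int)


def _onehot(y: np.ndarray) -> np.ndarray:
    out = np.zeros((y.size, 2))
    out[np.arange(y.size), y] = 1.0
    return out


def _fit_predict(
    feats: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: PipelineConfig,
) -> ConfusionCounts:
    # per-feature standardization fitted on the training part only
    mu = feats[train_idx].mean(axis=0)
    sd = feats[train_idx].std(axis=0)
    sd[sd == 0] = 1.0
    scaled = (feats - mu) / sd
    planes = np.stack([_cnn.reshape_features(v) for v in scaled])

    # carve a tuning fold out of the training part for ffo_tune
    y_tr = y[train_idx]
    if 0 < config.tune_fraction < 1 and np.unique(y_tr).size == 2:
        fit_idx, tune_idx = train_test_split(
            train_idx,
            test_size=config.tune_fraction,
            stratify=y_tr,
            random_state=config.seed,
        )
    else:
        fit_idx = tune_idx = train_idx

    spec = _cnn.canonical_spec()
    spec.epochs = config.epochs
    spec.batch_size = config.batch_size
    spec.learning_rate = config.learning_rate
    model = _cnn.build(spec, seed=config.seed)
    _cnn.train(model, planes[fit_idx], _onehot(y[fit_idx]), seed=config.seed)
    ffo_cfg = _ffo.FFOConfig(
        l=config.ffo_population,
        s=model.get_head().size,
        iter_max=config.ffo_iterations,
        seed=config.seed,
    )
    _cnn.ffo_tune(model, planes[tune_idx], _onehot(y[tune_idx]), ffo_cfg)
    preds = model.classify(planes[test_idx])
    return ConfusionCounts.from_predictions(y[test_idx], preds)


def run_harness(
    images: Sequence[LabeledImage],
    mode: tuple[str, float],
    config: Optional[PipelineConfig] = None,
    features: Optional[tuple[np.ndarray, np.ndarray]] = None,
) -> EvaluationReport:
    """Full pipeline under ``mode = ("kfold", k)`` or ``("split", train_pct)``.

    ``features`` may carry a precomputed ``prepare_planes`` result to avoid
    re-extracting when sweeping modes over the same images.
    """
    config = config or PipelineConfig()
    kind, value = mode
    feats, y = features if features is not None else prepare_planes(images, config)
    n = y.size

    folds: list[ConfusionCounts] = []
    if kind == "kfold":
        k = int(value)
        for test_idx in kfold_split(n, k, y, seed=config.seed):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            folds.append(_fit_predict(feats, y, train_idx, test_idx, config))
    elif kind == "split":
        pct = float(value)
        if not 0 < pct < 100:
            raise ValueError("training percentage must lie strictly between 0 and 100")
        train_idx, test_idx = train_test_split(
            np.arange(n),
            train_size=pct / 100.0,
            stratify=y,
            random_state=config.seed,
        )
        folds.append(_fit_predict(feats, y, train_idx, test_idx, config))
    else:
        raise ValueError(f"unknown harness mode {kind!r}")

    ms = [metrics(c) for c in folds]
    return EvaluationReport(
        mode=kind,
        parameter=float(value),
        folds=folds,
        fold_metrics=ms,
        mean_accuracy=float(np.mean([m.accuracy for m in ms])),
        mean_sensitivity=float(np.nanmean([m.sensitivity for m in ms])),
        mean_specificity=float(np.nanmean([m.specificity for m in ms])),
        seed=config.seed,
        config=config.echo(),
    )
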