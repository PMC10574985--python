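"""Evaluation suite: confusion-matrix metrics, one-vs-rest ROC, engineered
features, and the additive-white-Gaussian-noise robustness protocol.

The robustness protocol perturbs the classifier inputs with white Gaussian
noise at a grid of signal-to-noise ratios (dB, higher = cleaner) and traces
accuracy per activation variant; the infinite-SNR entry is the clean test
accuracy by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
import json
import warnings

import numpy as np
from scipy import stats as sstats
from sklearn.metrics import auc as _auc
from sklearn.metrics import cohen_kappa_score, confusion_matrix, roc_curve

from .io import EpochDataset

FEATURE_NAMES = ("mean", "crest_factor", "skewness", "variance",
                 "maximum", "minimum", "kurtosis")


@dataclass
class MetricsReport:
    """Confusion matrix plus the standard multiclass metric panel.

    Per-class rates are one-vs-rest; the headline sensitivity/specificity/
    precision/F-score are macro averages.  ``training_duration_s`` is
    informational only.
    """

    confusion: np.ndarray
    accuracy: float
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    f_score: np.ndarray
    kappa: float
    labels: np.ndarray
    roc: dict | None = None
    training_duration_s: float | None = None

    @property
    def macro_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity))

    @property
    def macro_specificity(self) -> float:
        return float(np.mean(self.specificity))

    @property
    def macro_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def macro_f_score(self) -> float:
        return float(np.mean(self.f_score))

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.tolist(),
            "labels": self.labels.tolist(),
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "precision": self.precision.tolist(),
            "f_score": self.f_score.tolist(),
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_precision": self.macro_precision,
            "macro_f_score": self.macro_f_score,
        }
        if self.roc is not None:
            d["auc"] = {str(k): v["auc"] for k, v in self.roc.items()}
        if self.training_duration_s is not None:
            d["training_duration_s"] = self.training_duration_s
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def confusion_and_metrics(y_true, y_pred, n_classes: int | None = None,
                          labels=None) -> MetricsReport:
    """Compute the full metric panel from true/predicted label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if labels is None:
        if n_classes is None:
            labels = np.unique(np.concatenate([y_true, y_pred]))
        else:
            labels = np.arange(n_classes)
    labels = np.asarray(labels)
    if n_classes is not None and (np.max(y_true) >= np.max(labels) + 1
                                  or np.min(y_true) < np.min(labels)):
        raise ValueError("labels out of range for the declared n_classes")
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        spec = np.where(tn + fp > 0, tn / (tn + fp), 0.0)
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        f1 = np.where(prec + sens > 0, 2 * prec * sens / (prec + sens), 0.0)
    return MetricsReport(
        confusion=cm,
        accuracy=float(tp.sum() / total),
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f_score=f1,
        kappa=float(cohen_kappa_score(y_true, y_pred, labels=labels)),
        labels=labels,
    )


def roc_ovr(y_true, class_scores) -> dict:
    """One-vs-rest ROC curve and trapezoidal AUC per class.

    ``class_scores`` rows must be probability vectors (sum to 1 within
    1e-6).  A class absent from (or filling all of) ``y_true`` has an
    undefined AUC, reported as NaN with ``degenerate=True``.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(class_scores, dtype=float)
    if scores.ndim != 2 or len(scores) != len(y_true):
        raise ValueError("class_scores must be (n_samples, n_classes)")
    if np.any(np.abs(scores.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("score rows must sum to 1 within 1e-6")
    out: dict = {}
    for k in range(scores.shape[1]):
        truth = (y_true == k).astype(int)
        if truth.min() == truth.max():
            out[k] = {"fpr": None, "tpr": None, "auc": float("nan"),
                      "degenerate": True}
            continue
        fpr, tpr, _ = roc_curve(truth, scores[:, k])
        out[k] = {"fpr": fpr, "tpr": tpr, "auc": float(_auc(fpr, tpr)),
                  "degenerate": False}
    return out


def add_awgn(signal: np.ndarray, snr_db: float,
             seed: int | np.random.Generator = 0) -> np.ndarray:
    """Add white Gaussian noise at the requested SNR (dB).

    ``snr_db = inf`` returns the signal unchanged.  Noise power is set so
    that ``10 log10(P_signal / P_noise) = snr_db`` against the empirical
    signal power.
    """
    x = np.asarray(signal, dtype=float)
    if np.isinf(snr_db) and snr_db > 0:
        return x.copy()
    p_sig = float(np.mean(x ** 2))
    if p_sig <= 0:
        raise ValueError("signal has zero power; SNR is undefined")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p_noise = p_sig / (10.0 ** (snr_db / 10.0))
    return x + rng.standard_normal(x.shape) * np.sqrt(p_noise)


@dataclass
class RobustnessCurve:
    """Accuracy per (activation variant, SNR, replicate)."""

    snr_grid_db: tuple[float, ...]
    accuracy: dict[str, np.ndarray]  # variant -> (n_snr, n_replicates)
    seed: int = 0

    def mean(self, variant: str) -> np.ndarray:
        return self.accuracy[variant].mean(axis=1)

    def sd(self, variant: str) -> np.ndarray:
        return self.accuracy[variant].std(axis=1)

    def to_frame(self):
        import pandas as pd

        rows = []
        for variant, acc in self.accuracy.items():
            for i, snr in enumerate(self.snr_grid_db):
                for r in range(acc.shape[1]):
                    rows.append({"variant": variant, "snr_db": snr,
                                 "replicate": r, "accuracy": acc[i, r]})
        return pd.DataFrame(rows)


def robustness_curve(models: dict, test_set, snr_grid_db,
                     replicates: int = 3, seed: int = 0) -> RobustnessCurve:
    """Trace accuracy under additive white Gaussian input noise.

    ``models`` maps variant name -> fitted classifier; noise is injected
    into the (preprocessed) classifier inputs.  The grid is sorted
    ascending; an infinite entry reproduces each model's clean accuracy
    exactly in every replicate.
    """
    grid = tuple(sorted(float(s) for s in snr_grid_db))
    if not grid:
        raise ValueError("snr_grid_db must be non-empty")
    if isinstance(test_set, EpochDataset):
        X, y = test_set.epochs, test_set.labels
    else:
        X, y = test_set
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    acc = {name: np.zeros((len(grid), replicates)) for name in models}
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(grid) * replicates)
    for i, snr in enumerate(grid):
        for r in range(replicates):
            rng = np.random.default_rng(streams[i * replicates + r])
            Xn = (X.copy() if np.isinf(snr)
                  else np.stack([add_awgn(x, snr, rng) for x in X]))
            for name, model in models.items():
                acc[name][i, r] = float((model.predict(Xn) == y).mean())
    return RobustnessCurve(grid, acc, seed)


def engineered_features(epoch: np.ndarray) -> np.ndarray:
    """Seven summary features per channel, in the order
    (mean, crest factor, skewness, variance, maximum, minimum, kurtosis).

    Crest factor is max(|x|)/RMS; variance is the population variance;
    kurtosis is the Fisher excess.  A zero-RMS channel has an undefined
    crest factor, reported as NaN with a warning.
    """
    x = np.atleast_2d(np.asarray(epoch, dtype=float))
    if x.shape[-1] < 2:
        raise ValueError("epoch must have at least 2 samples")
    rms = np.sqrt(np.mean(x ** 2, axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        crest = np.abs(x).max(axis=-1) / rms
    if np.any(rms == 0):
        warnings.warn("zero-RMS channel: crest factor undefined (NaN)")
        crest = np.where(rms == 0, np.nan, crest)
    feats = np.stack([
        x.mean(axis=-1),
        crest,
        sstats.skew(x, axis=-1),
        x.var(axis=-1),
        x.max(axis=-1),
        x.min(axis=-1),
        sstats.kurtosis(x, axis=-1),
    ], axis=-1)
    return feats[0] if np.asarray(epoch).ndim == 1 else feats
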