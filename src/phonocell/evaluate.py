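"""Evaluation machinery: confusion tables, background-aware sensitivity and
specificity, spatial class-map reconstruction, parameter-sweep maps and
majority-vote accuracy curves.

Conventions
-----------
* Confusion rows are the true class, columns the prediction, in the fixed
  order (normal, abnormal, background).
* Sensitivity/specificity treat *abnormal* (cancer) as positive.  A cell
  pixel predicted *background* counts as an error (false negative for an
  abnormal pixel, false positive contribution for a normal one), while
  true-background pixels are excluded entirely: a background call carries
  no diagnostic information, so it can only hurt, never help.
* Majority voting over k measurements of one cell uses the modal
  non-background prediction; ties (including all-background draws) count
  as failures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .acquisition import ClassLabel

logger = logging.getLogger(__name__)

__all__ = ["EvalReport", "AggregationCurve", "confusion_and_accuracy",
           "sensitivity_specificity", "reconstruct_class_map",
           "sweep_classification_map", "accuracy_vs_measurements"]

_CLASS_ORDER = (ClassLabel.NORMAL, ClassLabel.ABNORMAL, ClassLabel.BACKGROUND)


@dataclass
class EvalReport:
    """Confusion matrix and derived rates for one evaluation."""

    confusion: np.ndarray  # (3, 3) counts, rows = true class
    overall_accuracy: float
    per_class_accuracy: np.ndarray  # fraction correct per true class
    sensitivity: float
    specificity: float
    n_samples: int

    def __post_init__(self) -> None:
        c = np.asarray(self.confusion)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("confusion must be a non-negative 3x3 matrix")
        if int(c.sum()) != self.n_samples:
            raise ValueError("confusion entries must sum to n_samples")

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_order": [c.name.lower() for c in _CLASS_ORDER],
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": list(map(float, self.per_class_accuracy)),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_samples": self.n_samples,
        }


@dataclass
class AggregationCurve:
    """Success probability of majority-vote cell classification vs k."""

    k_values: np.ndarray
    success_probability: np.ndarray
    n_repetitions: int = 250

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.success_probability = np.asarray(self.success_probability, dtype=float)
        if self.k_values.shape != self.success_probability.shape:
            raise ValueError("one success probability per k is required")
        if ((self.success_probability < 0) | (self.success_probability > 1)).any():
            raise ValueError("probabilities must lie in [0, 1]")


def confusion_and_accuracy(predictions, labels,
                           subsample: int | None = None,
                           rng_seed: int | None = None) -> EvalReport:
    """Tally a 3x3 confusion matrix and derived rates.

    ``predictions``/``labels`` are ClassLabel-valued arrays (or
    Prediction objects for the former).  ``subsample`` draws a seeded
    random subset first, mirroring evaluation on a fixed random slice of
    the test set.
    """
    pred = np.asarray([int(p.label) if hasattr(p, "label") else int(p)
                       for p in predictions])
    true = np.asarray([int(l) for l in labels])
    if pred.shape != true.shape:
        raise ValueError("predictions and labels must have equal length")
    if subsample is not None and subsample < true.size:
        idx = np.random.default_rng(rng_seed).choice(
            true.size, size=subsample, replace=False)
        pred, true = pred[idx], true[idx]
    conf = np.zeros((3, 3), dtype=int)
    np.add.at(conf, (true, pred), 1)
    n = int(conf.sum())
    acc = float(np.trace(conf) / n) if n else float("nan")
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.diag(conf) / conf.sum(axis=1)
    sens, spec = sensitivity_specificity(conf)
    return EvalReport(conf, acc, per_class, sens, spec, n)


def sensitivity_specificity(confusion) -> tuple[float, float]:
    """Background-aware sensitivity and specificity (positive = abnormal).

    Accepts an EvalReport or a raw 3x3 confusion matrix.  False
    *background* predictions count toward false negatives (abnormal
    pixels) and false positives (normal pixels); the true-background row
    is excluded as inconclusive.  Zero denominators yield NaN rather than
    raising.
    """
    c = np.asarray(confusion.confusion if isinstance(confusion, EvalReport)
                   else confusion, dtype=float)
    nrm, ab, bg = (int(ClassLabel.NORMAL), int(ClassLabel.ABNORMAL),
                   int(ClassLabel.BACKGROUND))
    tp = c[ab, ab]
    fn = c[ab, nrm] + c[ab, bg]
    tn = c[nrm, nrm]
    fp = c[nrm, ab] + c[nrm, bg]
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return float(sens), float(spec)


def reconstruct_class_map(predictions: Sequence,
                          grid_shape: tuple[int, int],
                          pixels: Sequence[tuple[int, int]] | None = None,
                          sentinel: int = -1) -> np.ndarray:
    """Arrange per-pixel predictions back into the scan grid.

    ``pixels`` gives each prediction's (row, col); omitted, predictions
    are assumed to cover the grid in row-major order.  Missing pixels are
    filled with ``sentinel`` and reported via a warning.
    """
    rows, cols = grid_shape
    labels = [int(p.label) if hasattr(p, "label") else int(p)
              for p in predictions]
    if pixels is None:
        if len(labels) != rows * cols:
            raise ValueError("prediction count must equal grid size when "
                             "pixel positions are omitted")
        return np.asarray(labels, dtype=int).reshape(rows, cols)
    out = np.full((rows, cols), sentinel, dtype=int)
    for lab, (r, c) in zip(labels, pixels):
        out[r, c] = lab
    n_missing = int((out == sentinel).sum())
    if n_missing:
        logger.warning("class map: %d pixel(s) missing (sentinel %d)",
                       n_missing, sentinel)
    return out


def sweep_classification_map(model, sweep, image_size: int = 64):
    """Classify a (nu, alpha0) parameter sweep with a trained model.

    ``sweep`` is the output of ``simulate_parameter_sweep``: (MaterialPoint,
    TimeTrace) pairs.  Traces at the same grid point are predicted
    individually and combined by majority (ties broken toward the lowest
    class index).  Returns ``(label_grid, nu_values, alpha_values)`` with
    label_grid[i, j] for nu_values[i], alpha_values[j].
    """
    from .cnn import predict_proba
    from .gasf import encode_traces_array

    mats = [m for m, _ in sweep]
    traces = np.stack([t.samples for _, t in sweep])
    images = encode_traces_array(traces, target_size=image_size)
    pred = predict_proba(model, images).argmax(axis=1)
    nus = sorted({m.sound_velocity for m in mats})
    alphas = sorted({m.attenuation_coeff for m in mats})
    nu_ix = {v: i for i, v in enumerate(nus)}
    al_ix = {v: i for i, v in enumerate(alphas)}
    votes = np.zeros((len(nus), len(alphas), 3), dtype=int)
    for m, p in zip(mats, pred):
        votes[nu_ix[m.sound_velocity], al_ix[m.attenuation_coeff], p] += 1
    grid = votes.argmax(axis=2)
    return grid, np.asarray(nus), np.asarray(alphas)


def _vote(draw: np.ndarray) -> int | None:
    """Modal non-background class of one draw; None on tie/no information."""
    counts = np.bincount(draw, minlength=3)
    nrm, ab = counts[int(ClassLabel.NORMAL)], counts[int(ClassLabel.ABNORMAL)]
    if nrm == ab:  # includes the all-background case
        return None
    return int(ClassLabel.NORMAL) if nrm > ab else int(ClassLabel.ABNORMAL)


def accuracy_vs_measurements(cell_predictions: Mapping,
                             k_values: Sequence[int],
                             n_repetitions: int = 250,
                             rng_seed: int | None = None,
                             pooled: bool = False) -> AggregationCurve:
    """Majority-vote success probability against the number of measurements.

    ``cell_predictions`` maps cell_id -> (predicted labels on that cell's
    cell pixels, true cell class).  For each cell and k, k predictions
    are drawn without replacement and the cell is classified by the modal
    non-background class; a tie (or an all-background draw) counts as a
    failure.  Background predictions never vote but still consume draws.
    The curve averages per-cell success rates with equal cell weight
    (``pooled=True`` pools all draws instead).
    """
    rng = np.random.default_rng(rng_seed)
    k_values = np.asarray(sorted(k_values), dtype=int)
    if (k_values < 1).any():
        raise ValueError("k values must be >= 1")
    per_cell = []
    weights = []
    for cid, (preds, true_class) in cell_predictions.items():
        preds = np.asarray([int(p) for p in preds])
        true_class = int(true_class)
        successes = np.zeros(k_values.size)
        for ki, k in enumerate(k_values):
            if k > preds.size:
                raise ValueError(
                    f"k={k} exceeds the {preds.size} predictions of cell {cid}")
            hits = 0
            for _ in range(n_repetitions):
                draw = preds[rng.choice(preds.size, size=k, replace=False)]
                hits += (_vote(draw) == true_class)
            successes[ki] = hits / n_repetitions
        per_cell.append(successes)
        weights.append(preds.size)
    if not per_cell:
        raise ValueError("no cells to aggregate")
    per_cell = np.asarray(per_cell)
    if pooled:
        w = np.asarray(weights, dtype=float)
        prob = (per_cell * w[:, None]).sum(axis=0) / w.sum()
    else:
        prob = per_cell.mean(axis=0)
    return AggregationCurve(k_values, prob, n_repetitions)
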