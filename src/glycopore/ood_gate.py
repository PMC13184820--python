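"""Class-conditional KDE acceptance gate for out-of-distribution events.

For each trained class a Gaussian kernel density estimator is fitted over the
standardized selected-feature space (the same space the classifier sees). The
initial per-class acceptance threshold is the 5th percentile of that class's
training log-likelihoods; calibration then moves each threshold to the
(1 − coverage) quantile of the class's *validation* log-likelihoods so that
the target per-class coverage (70% by default) holds on held-out data. At
inference an event is scored only under its predicted class's estimator;
events below threshold are labelled UNK ("not accepted"), and metrics are
reported both on all events and on the accepted-only subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, balanced_accuracy_score, f1_score
from sklearn.neighbors import KernelDensity

from .trace_io import ValidationError

__all__ = [
    "UNK",
    "GateModel",
    "fit_gate",
    "calibrate_gate",
    "gate_log_likelihood",
    "apply_gate",
    "accepted_only_metrics",
    "mixture_composition",
]

UNK = "UNK"


@dataclass
class GateModel:
    """Per-class KDEs with per-class log-likelihood acceptance thresholds."""

    kdes: dict                    # class -> fitted KernelDensity
    thresholds: dict              # class -> log-likelihood cutoff
    calibration_state: str        # "initial" | "calibrated"
    target_coverage: float = 0.70
    initial_percentile: float = 5.0
    bandwidths: dict = field(default_factory=dict)


def _scott_bandwidth(X: np.ndarray, floor: float) -> float:
    n, d = X.shape
    sd = float(np.mean(np.std(X, axis=0)))
    if sd == 0:
        sd = 1.0
    return max(sd * n ** (-1.0 / (d + 4)), floor)


def fit_gate(
    X_train: np.ndarray,
    labels,
    initial_percentile: float = 5.0,
    target_coverage: float = 0.70,
    bandwidth_floor: float = 1e-2,
    min_class_points: int = 50,
) -> GateModel:
    """Fit one Gaussian KDE per class; initial thresholds at the 5th percentile.

    Thresholds use median-unbiased quantiles (the log-likelihood samples are
    left-skewed), so "5% of a class's own training points fall below its
    threshold" holds up to the interpolation convention. Bandwidths follow a Scott-type rule per class
    with a configurable floor against singular (constant-column) classes.
    """
    labels = np.asarray(labels)
    kdes, thresholds, bandwidths = {}, {}, {}
    for cls in np.unique(labels):
        Xc = X_train[labels == cls]
        if Xc.shape[0] < min_class_points:
            raise ValidationError(
                f"class {cls!r} has {Xc.shape[0]} training points (< {min_class_points})"
            )
        bw = _scott_bandwidth(Xc, bandwidth_floor)
        if bw == bandwidth_floor:
            warnings.warn(f"bandwidth floor applied for class {cls!r}", stacklevel=2)
        kde = KernelDensity(kernel="gaussian", bandwidth=bw).fit(Xc)
        ll = kde.score_samples(Xc)
        kdes[cls] = kde
        # median-unbiased quantiles: log-likelihood samples are left-skewed
        thresholds[cls] = float(
            np.percentile(ll, initial_percentile, method="median_unbiased")
        )
        bandwidths[cls] = bw
    return GateModel(
        kdes=kdes,
        thresholds=thresholds,
        calibration_state="initial",
        target_coverage=target_coverage,
        initial_percentile=initial_percentile,
        bandwidths=bandwidths,
    )


def calibrate_gate(
    gate: GateModel, X_val: np.ndarray, labels, coverage: float | None = None
) -> GateModel:
    """Move each class threshold to the (1 − coverage) validation quantile.

    Only thresholds change; the densities stay as fitted on training data. A
    class absent from validation keeps its initial threshold (warned).
    coverage = 1 accepts everything, coverage = 0 rejects everything.
    """
    coverage = gate.target_coverage if coverage is None else coverage
    if not (0.0 <= coverage <= 1.0):
        raise ValidationError("coverage must lie in [0, 1]")
    labels = np.asarray(labels)
    thresholds = dict(gate.thresholds)
    for cls, kde in gate.kdes.items():
        mask = labels == cls
        if not mask.any():
            warnings.warn(f"class {cls!r} absent from validation; keeping initial threshold",
                          stacklevel=2)
            continue
        ll = kde.score_samples(X_val[mask])
        if coverage >= 1.0:
            thresholds[cls] = -np.inf
        elif coverage <= 0.0:
            thresholds[cls] = np.inf
        else:
            thresholds[cls] = float(
                np.quantile(ll, 1.0 - coverage, method="median_unbiased")
            )
    return GateModel(
        kdes=gate.kdes,
        thresholds=thresholds,
        calibration_state="calibrated",
        target_coverage=coverage,
        initial_percentile=gate.initial_percentile,
        bandwidths=gate.bandwidths,
    )


def gate_log_likelihood(gate: GateModel, cls, X: np.ndarray) -> np.ndarray:
    """Log-likelihood of rows of X under the class-``cls`` density."""
    if cls not in gate.kdes:
        raise ValidationError(f"class {cls!r} unknown to the gate")
    return gate.kdes[cls].score_samples(X)


def apply_gate(gate: GateModel, predictions, X: np.ndarray):
    """Gate decisions for predicted events.

    Each event is scored only under its *predicted* class's KDE; events whose
    log-likelihood falls below that class's threshold become UNK. Predictions
    for labels unknown to the gate become UNK with reason "unknown_class".
    Returns (gated labels, accepted mask, reasons).
    """
    predictions = np.asarray(predictions, dtype=object)
    n = predictions.size
    gated = predictions.copy()
    accepted = np.zeros(n, dtype=bool)
    reasons = np.array(["accepted"] * n, dtype=object)
    for cls in np.unique(predictions):
        idx = np.flatnonzero(predictions == cls)
        if cls not in gate.kdes:
            gated[idx] = UNK
            reasons[idx] = "unknown_class"
            continue
        ll = gate.kdes[cls].score_samples(X[idx])
        below = ll < gate.thresholds[cls]
        gated[idx[below]] = UNK
        reasons[idx[below]] = "below_threshold"
        accepted[idx[~below]] = True
    return gated, accepted, reasons


def accepted_only_metrics(truth, predictions, accepted) -> dict:
    """Accuracy / macro-F1 / balanced accuracy, overall and accepted-only.

    Also reports the per-class acceptance rate (keyed by true label). With
    zero accepted events the accepted-only metrics are NaN markers.
    """
    truth = np.asarray(truth, dtype=object)
    predictions = np.asarray(predictions, dtype=object)
    accepted = np.asarray(accepted, dtype=bool)

    def _metrics(t, p):
        if t.size == 0:
            return {"accuracy": float("nan"), "macro_f1": float("nan"),
                    "balanced_accuracy": float("nan")}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return {
                "accuracy": float(accuracy_score(t, p)),
                "macro_f1": float(f1_score(t, p, average="macro")),
                "balanced_accuracy": float(balanced_accuracy_score(t, p)),
            }

    per_class_acceptance = {
        str(cls): float(np.mean(accepted[truth == cls])) for cls in np.unique(truth)
    }
    return {
        "all": _metrics(truth, predictions),
        "accepted_only": _metrics(truth[accepted], predictions[accepted]),
        "acceptance_rate": float(np.mean(accepted)) if truth.size else float("nan"),
        "per_class_acceptance": per_class_acceptance,
    }


def mixture_composition(gated_calls) -> pd.Series:
    """Proportions over {classes} ∪ {UNK}; sums to 1."""
    calls = pd.Series(np.asarray(gated_calls, dtype=object))
    if calls.size == 0:
        raise ValidationError("no calls to summarize")
    return calls.value_counts(normalize=True).sort_index()
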