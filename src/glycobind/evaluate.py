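"""Binder/non-binder classification and comparison metrics.

Continuous model outputs (fraction bound) and experimental readouts
(liquid-array fold change, microarray intensity) are reduced to binary
binder calls with strict thresholds, compared in a 2×2 confusion table,
and summarized by eleven quality metrics: the four counts' derived rates
(TPR, TNR, PPV, NPV), Jaccard index, accuracy, F1, balanced accuracy,
informedness, and the Matthews correlation coefficient in its
rate-product form

    MCC = sqrt(TPR·TNR·PPV·NPV) − sqrt((1−TPR)(1−TNR)(1−NPV)(1−PPV)),

which is algebraically identical to the covariance form whenever every
margin is non-zero.  Ratios with a zero denominator are reported as NaN
with a warning — silent zeros would corrupt cross-model comparisons.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricSet:
    counts: ConfusionCounts
    jaccard: float
    accuracy: float
    f1: float
    tpr: float
    tnr: float
    ppv: float
    npv: float
    balanced_accuracy: float
    informedness: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.counts.tp,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
            "TN": self.counts.tn,
            "jaccard": self.jaccard,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "ppv": self.ppv,
            "npv": self.npv,
            "balanced_accuracy": self.balanced_accuracy,
            "informedness": self.informedness,
            "mcc": self.mcc,
        }


def threshold_predictions(f_values, threshold: float = 0.0, strict: bool = True) -> np.ndarray:
    """Binder iff value > threshold (strict) or ≥ threshold.

    The default (f > 0, strict) calls any positive predicted fraction bound
    a binder; a prediction of exactly zero is a non-binder.
    """
    f_values = np.asarray(f_values, dtype=float)
    return f_values > threshold if strict else f_values >= threshold


def combine_experiments(
    liga_fc=None,
    array_intensity=None,
    fc_threshold: float = 1.5,
    intensity_threshold: float = 1000.0,
) -> np.ndarray:
    """Observed binder call: (FC > 1.5) OR (intensity > 1000), strict.

    Either modality may be missing per observation (NaN); a missing
    measurement is treated as non-positive evidence.  Observations missing
    both modalities are an error.
    """
    if liga_fc is None and array_intensity is None:
        raise ValueError("at least one experimental modality is required")
    fc = np.asarray(liga_fc, dtype=float) if liga_fc is not None else None
    inten = np.asarray(array_intensity, dtype=float) if array_intensity is not None else None
    if fc is not None and inten is not None and fc.shape != inten.shape:
        raise ValueError("modalities must be aligned")
    n = len(fc) if fc is not None else len(inten)
    fc = np.full(n, np.nan) if fc is None else fc
    inten = np.full(n, np.nan) if inten is None else inten
    both_missing = np.isnan(fc) & np.isnan(inten)
    if both_missing.any():
        raise ValueError(f"{int(both_missing.sum())} observations missing both modalities")
    fc_pos = np.where(np.isnan(fc), False, fc > fc_threshold)
    in_pos = np.where(np.isnan(inten), False, inten > intensity_threshold)
    return fc_pos | in_pos


def confusion(predicted, observed) -> ConfusionCounts:
    """Standard 2×2 counts from aligned boolean classifications."""
    predicted = np.asarray(predicted, dtype=bool)
    observed = np.asarray(observed, dtype=bool)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed must be aligned")
    return ConfusionCounts(
        tp=int(np.sum(predicted & observed)),
        fp=int(np.sum(predicted & ~observed)),
        fn=int(np.sum(~predicted & observed)),
        tn=int(np.sum(~predicted & ~observed)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("metric %s undefined (zero denominator); reporting NaN", name)
        return math.nan
    return num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """The eleven comparison metrics from a 2×2 table."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    tpr = _ratio(tp, tp + fn, "TPR")
    tnr = _ratio(tn, fp + tn, "TNR")
    ppv = _ratio(tp, tp + fp, "PPV")
    npv = _ratio(tn, tn + fn, "NPV")
    if any(math.isnan(v) for v in (tpr, tnr, ppv, npv)):
        mcc = math.nan
        logger.warning("MCC undefined (a constituent rate is NaN)")
    else:
        mcc = math.sqrt(tpr * tnr * ppv * npv) - math.sqrt(
            (1 - tpr) * (1 - tnr) * (1 - npv) * (1 - ppv)
        )
    return MetricSet(
        counts=c,
        jaccard=_ratio(tp, tp + fn + fp, "Jaccard"),
        accuracy=(tp + tn) / c.total,
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "F1"),
        tpr=tpr,
        tnr=tnr,
        ppv=ppv,
        npv=npv,
        balanced_accuracy=(tpr + tnr) / 2,
        informedness=tpr + tnr - 1,
        mcc=mcc,
    )
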