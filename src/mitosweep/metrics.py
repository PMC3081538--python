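"""Confusion-matrix statistics, FDR and class-prior-corrected FDR.

Sensitivity is recall of the mitochondrial (positive) class, TP/(TP+FN);
specificity is TN/(TN+FP).  The plain false discovery rate FP/(FP+TP) is
computed on the test sample, whose 100:630 class mix is far richer in
mitochondrial proteins than the genome.  The corrected FDR rescales to a
genome-wide prior — roughly 1500 mitochondrial proteins among 21,000
nuclear genes:

    cFDR = (1 - specificity) / ((1 - specificity) + sensitivity * q),

with ``q`` defaulting to 1500/21000.  All metrics live in [0, 1] internally;
reports render them as percentages.

Conventions (chosen so aggregates over many resampling runs are never
poisoned by a single degenerate split): FDR is 0 when there are no positive
predictions; cFDR is 0 when specificity is exactly 1.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

#: Genome-wide prior: ~1500 mitochondrial proteins of ~21,000 nuclear genes.
DEFAULT_PRIOR_FRACTION = 1500.0 / 21000.0


class UndefinedMetricError(ValueError):
    """A metric's defining ratio has an empty denominator."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same shape")
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN): recall of mitochondrial proteins."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positives in the test set")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP): recall of non-mitochondrial proteins."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negatives in the test set")
    return c.tn / (c.tn + c.fp)


def fdr(c: ConfusionCounts) -> float:
    """FP / (FP + TP); 0 when nothing was predicted positive."""
    if c.fp + c.tp == 0:
        return 0.0
    return c.fp / (c.fp + c.tp)


def cfdr(sens: float, spec: float, prior_fraction: float = DEFAULT_PRIOR_FRACTION) -> float:
    """Class-prior-corrected FDR.

    ``(1-spec) / ((1-spec) + sens * prior_fraction)``; returns 0 when the
    numerator is 0 (perfect specificity), including the doubly-degenerate
    ``sens == 0`` case.
    """
    if not 0.0 <= sens <= 1.0:
        raise ValueError(f"sensitivity {sens} outside [0, 1]")
    if not 0.0 <= spec <= 1.0:
        raise ValueError(f"specificity {spec} outside [0, 1]")
    if not 0.0 < prior_fraction < 1.0:
        raise ValueError(f"prior_fraction {prior_fraction} outside (0, 1)")
    fp_rate = 1.0 - spec
    if fp_rate == 0.0:
        return 0.0
    return fp_rate / (fp_rate + sens * prior_fraction)


def aggregate(values) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of run-level metric values.

    Implemented with the stdlib ``statistics`` routines; a single value has
    mean itself and SD ``nan``.
    """
    values = list(values)
    if not values:
        raise ValueError("cannot aggregate an empty list")
    mean = statistics.fmean(values)
    sd = statistics.stdev(values) if len(values) >= 2 else math.nan
    return mean, sd


def welch_z(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch-type z comparison of two group means.

    Returns ``(difference, z, p)`` with ``difference = mean1 - mean2``,
    ``z = difference / sqrt(sd1^2/n1 + sd2^2/n2)`` and a two-sided Gaussian
    p-value.  With both SDs zero the statistic is undefined for equal means
    (raises); for unequal means it is ±inf with p = 0.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("welch_z needs n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    diff = mean1 - mean2
    se = math.sqrt(sd1 * sd1 / n1 + sd2 * sd2 / n2)
    if se == 0.0:
        if diff == 0.0:
            raise UndefinedMetricError("welch_z undefined: zero variance and equal means")
        return diff, math.copysign(math.inf, diff), 0.0
    z = diff / se
    p = 2.0 * norm.sf(abs(z))
    return diff, z, p


def gaussian_ci_halfwidth(sd: float, confidence: float = 0.95) -> float:
    """Half-width of the Gaussian central interval: ``z_{(1+conf)/2} * sd``.

    With run-to-run sensitivity SDs of ~5 percentage points this is the
    ~±10% uncertainty band quoted for even the best tool combinations.
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    return float(norm.ppf(0.5 + confidence / 2.0) * sd)
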