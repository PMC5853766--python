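"""Diagnostic-accuracy statistics with exact binomial confidence intervals.

The five standard proportions of a binary diagnostic test —

* diagnostic accuracy = (TP+TN)/(TP+FP+FN+TN)
* sensitivity          = TP/(TP+FN)
* specificity          = TN/(TN+FP)
* positive predictive value = TP/(TP+FP)
* negative predictive value = TN/(TN+FN)

— each reported with an exact (Clopper–Pearson) two-sided confidence
interval on its (numerator, denominator) pair. The five-class predictions
are dichotomized as normal vs abnormal (any of S3 / S4 / systolic murmur /
diastolic murmur counts as positive). A metric whose denominator is zero
is reported as undefined, never as 0 or 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import POSITIVE_CLASSES, SoundClass
from .errors import ConfigurationError

__all__ = ["ConfusionCounts", "ProportionCI", "MetricEstimate", "DiagnosticMetrics",
           "binarize_label", "confusion", "clopper_pearson", "diagnostic_metrics",
           "evaluate_dataset", "confusion_matrix_5class", "format_metrics_table"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")
        if self.total < 1:
            raise ConfigurationError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ProportionCI:
    """An exact binomial confidence interval for k successes in n trials."""

    k: int
    n: int
    level: float
    lower: float
    upper: float

    @property
    def estimate(self) -> float:
        return self.k / self.n


@dataclass(frozen=True)
class MetricEstimate:
    """One diagnostic proportion with its CI; undefined when n == 0."""

    name: str
    k: int | None
    n: int | None
    ci: ProportionCI | None

    @property
    def defined(self) -> bool:
        return self.ci is not None

    @property
    def value(self) -> float | None:
        return self.ci.estimate if self.ci else None

    def as_percent(self) -> str:
        """Whole-percent rendering, e.g. ``90 (73-98)``; em dash if undefined."""
        if not self.ci:
            return "—"
        return (f"{round(100 * self.ci.estimate):.0f} "
                f"({round(100 * self.ci.lower):.0f}-{round(100 * self.ci.upper):.0f})")


@dataclass(frozen=True)
class DiagnosticMetrics:
    counts: ConfusionCounts
    accuracy: MetricEstimate
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate

    def __iter__(self):
        yield from (self.accuracy, self.sensitivity, self.specificity, self.ppv, self.npv)


def binarize_label(cls: SoundClass | str) -> str:
    """Dichotomize the 5-way label: NORMAL -> 'negative', else 'positive'."""
    cls = SoundClass(cls)
    return "positive" if cls in POSITIVE_CLASSES else "negative"


def confusion(predictions, truths) -> ConfusionCounts:
    """Binary confusion counts from 5-class (or binary) labels."""
    if len(predictions) != len(truths):
        raise ConfigurationError(
            f"length mismatch: {len(predictions)} predictions, {len(truths)} truths"
        )
    if len(predictions) == 0:
        raise ConfigurationError("need at least one prediction")

    def _bin(v) -> str:
        if isinstance(v, str) and v in ("positive", "negative"):
            return v
        return binarize_label(v)

    tp = fp = fn = tn = 0
    for p, t in zip(predictions, truths):
        pb, tb = _bin(p), _bin(t)
        if tb == "positive":
            tp += pb == "positive"
            fn += pb == "negative"
        else:
            fp += pb == "positive"
            tn += pb == "negative"
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson(k: int, n: int, level: float = 0.95) -> ProportionCI:
    """Exact two-sided binomial CI via Beta quantiles.

    lower = BetaInv(alpha/2; k, n-k+1) (0 when k=0),
    upper = BetaInv(1-alpha/2; k+1, n-k) (1 when k=n).
    """
    if not 0 <= k <= n or n < 1:
        raise ConfigurationError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < level < 1:
        raise ConfigurationError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ProportionCI(k=int(k), n=int(n), level=level, lower=lower, upper=upper)


def _metric(name: str, k: int, n: int, level: float) -> MetricEstimate:
    if n == 0:
        return MetricEstimate(name=name, k=None, n=None, ci=None)
    return MetricEstimate(name=name, k=k, n=n, ci=clopper_pearson(k, n, level))


def diagnostic_metrics(c: ConfusionCounts, level: float = 0.95) -> DiagnosticMetrics:
    """The five diagnostic proportions with exact CIs from confusion counts."""
    return DiagnosticMetrics(
        counts=c,
        accuracy=_metric("accuracy", c.tp + c.tn, c.total, level),
        sensitivity=_metric("sensitivity", c.tp, c.tp + c.fn, level),
        specificity=_metric("specificity", c.tn, c.tn + c.fp, level),
        ppv=_metric("ppv", c.tp, c.tp + c.fp, level),
        npv=_metric("npv", c.tn, c.tn + c.fn, level),
    )


def confusion_matrix_5class(predictions, truths) -> pd.DataFrame:
    """Full 5x5 confusion matrix (rows = truth, columns = prediction)."""
    order = [c.value for c in SoundClass]
    mat = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for p, t in zip(predictions, truths):
        mat.loc[SoundClass(t).value, SoundClass(p).value] += 1
    return mat


def evaluate_dataset(predictions, truths, subgroups=None,
                     level: float = 0.95) -> pd.DataFrame:
    """Per-subgroup diagnostic-metric table (plus a total row).

    ``subgroups`` maps a subgroup name to a boolean/index mask aligned with
    the recordings; the total row is always included.
    """
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ConfigurationError("predictions and truths must align")
    groups: dict[str, np.ndarray] = {"total": np.ones(len(truths), dtype=bool)}
    if subgroups:
        for name, mask in subgroups.items():
            mask = np.asarray(mask)
            if mask.dtype != bool:
                raise ConfigurationError(f"subgroup {name!r} must be a boolean mask")
            if mask.shape != (len(truths),):
                raise ConfigurationError(
                    f"subgroup {name!r} mask length {mask.shape} does not match "
                    f"{len(truths)} recordings"
                )
            groups[name] = mask
    rows = []
    for name, mask in groups.items():
        preds = [p for p, m in zip(predictions, mask) if m]
        trs = [t for t, m in zip(truths, mask) if m]
        if not preds:
            continue
        m = diagnostic_metrics(confusion(preds, trs), level=level)
        row = {"subgroup": name, "n": m.counts.total,
               "tp": m.counts.tp, "fp": m.counts.fp,
               "fn": m.counts.fn, "tn": m.counts.tn}
        for est in m:
            row[est.name] = est.value
            row[f"{est.name}_ci"] = est.as_percent()
        rows.append(row)
    return pd.DataFrame(rows)


def format_metrics_table(m: DiagnosticMetrics) -> str:
    """Human-readable report of the five metrics as whole percents."""
    label = {"accuracy": "Diagnostic accuracy", "sensitivity": "Sensitivity",
             "specificity": "Specificity", "ppv": "Positive predictive value",
             "npv": "Negative predictive value"}
    lines = [f"n={m.counts.total}  TP={m.counts.tp} FP={m.counts.fp} "
             f"FN={m.counts.fn} TN={m.counts.tn}"]
    for est in m:
        lines.append(f"  {label[est.name]:<26s} {est.as_percent()}")
    return "\n".join(lines)
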