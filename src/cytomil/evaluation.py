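"""Diagnostic performance and inter-rater agreement statistics.

Covers the metric suite used to judge a slide-level classifier against an
adjudicated gold standard: confusion-matrix metrics (accuracy, sensitivity,
specificity, displayed as half-up-rounded percentages), the ROC curve with
trapezoidal AUC and a percentile-bootstrap 95% CI, and a pairwise Kendall
tau-b matrix for agreement between raters (tau-b's tie correction is what
lets a rater identical to the gold standard score exactly 1.0 on binary
reads; the uncorrected statistic cannot).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .seeding import substream


def _pct(x: float) -> float:
    """Fraction -> percentage rounded half-up to 2 decimals (display scale)."""
    return float(Decimal(repr(x * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1")
    return a.astype(int)


@dataclass
class ConfusionSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float  # percent, 2 dp
    sensitivity: float
    specificity: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_misclassified(self) -> int:
        return self.fp + self.fn


def confusion_metrics(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionSummary:
    """Confusion counts and accuracy/sensitivity/specificity (as percentages)."""
    predicted = _check_binary(predicted, "predicted")
    truth = _check_binary(truth, "truth")
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    tp = int(((predicted == 1) & (truth == 1)).sum())
    fp = int(((predicted == 1) & (truth == 0)).sum())
    tn = int(((predicted == 0) & (truth == 0)).sum())
    fn = int(((predicted == 0) & (truth == 1)).sum())
    n = tp + fp + tn + fn
    return ConfusionSummary(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=_pct((tp + tn) / n),
        sensitivity=_pct(tp / (tp + fn)) if tp + fn else float("nan"),
        specificity=_pct(tn / (tn + fp)) if tn + fp else float("nan"),
    )


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    curve: list[tuple[float, float]]  # (fpr, tpr)


def roc_auc(
    scores: Sequence[float], truth: Sequence[int], n_boot: int = 2000, seed: int = 0
) -> RocResult:
    """Empirical ROC with trapezoidal AUC and a percentile-bootstrap 95% CI.

    The trapezoidal AUC over the empirical ROC equals the Mann-Whitney
    probability that a random positive outranks a random negative (ties
    counting half).  The CI resamples slides with replacement ``n_boot``
    times (seeded); degenerate single-class resamples are skipped.
    """
    scores = np.asarray(scores, dtype=float)
    truth = _check_binary(truth, "truth")
    if len(scores) != len(truth):
        raise ValueError("scores and truth must have equal length")
    if truth.min() == truth.max():
        raise ValueError("both classes must be present to compute an ROC")
    fpr, tpr, _ = roc_curve(truth, scores)
    point = float(_trapezoid_auc(fpr, tpr))

    rng = substream(seed, "bootstrap")
    n = len(truth)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        t = truth[idx]
        if t.min() == t.max():
            continue
        f, tp_, _ = roc_curve(t, scores[idx])
        boots.append(_trapezoid_auc(f, tp_))
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return RocResult(auc=point, ci_low=float(lo), ci_high=float(hi), curve=list(zip(fpr.tolist(), tpr.tolist())))


@dataclass
class AgreementMatrix:
    rater_ids: list[str]
    tau: np.ndarray  # symmetric, NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.tau, index=self.rater_ids, columns=self.rater_ids)


def kendall_tau_matrix(reads: pd.DataFrame) -> AgreementMatrix:
    """Pairwise Kendall tau-b between raters.

    ``reads``: one column per rater, one row per slide, binary values.
    A constant rater has no rank variance, so its tau is undefined and
    recorded as NaN (including its diagonal), never as 0.
    """
    if reads.shape[1] < 2:
        raise ValueError("need at least two raters")
    if reads.isna().any().any():
        raise ValueError("reads must not contain missing values")
    raters = list(reads.columns)
    k = len(raters)
    tau = np.full((k, k), np.nan)
    constant = [reads[r].nunique() <= 1 for r in raters]
    for i in range(k):
        if not constant[i]:
            tau[i, i] = 1.0
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                continue
            t, _ = kendalltau(reads[raters[i]], reads[raters[j]], variant="b")
            tau[i, j] = tau[j, i] = float(t)
    return AgreementMatrix(rater_ids=[str(r) for r in raters], tau=tau)


@dataclass
class DiagnosticReport:
    """Bundle of the evaluation outputs for one test set."""

    confusion: ConfusionSummary
    roc: Optional[RocResult] = None
    agreement: Optional[AgreementMatrix] = None

    def to_dict(self) -> dict:
        out = {
            "n_slides": self.confusion.n,
            "tp": self.confusion.tp,
            "fp": self.confusion.fp,
            "tn": self.confusion.tn,
            "fn": self.confusion.fn,
            "n_misclassified": self.confusion.n_misclassified,
            "accuracy_pct": self.confusion.accuracy,
            "sensitivity_pct": self.confusion.sensitivity,
            "specificity_pct": self.confusion.specificity,
        }
        if self.roc is not None:
            out["auc"] = self.roc.auc
            out["auc_ci95"] = [self.roc.ci_low, self.roc.ci_high]
        if self.agreement is not None:
            out["kendall_tau"] = {
                "raters": self.agreement.rater_ids,
                "tau": [[None if np.isnan(v) else float(v) for v in row] for row in self.agreement.tau],
            }
        return out


def evaluate_predictions(
    predictions: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    extra_raters: Optional[pd.DataFrame] = None,
) -> DiagnosticReport:
    """Full report from a predictions table with ``true_label`` column.

    ``extra_raters`` (optional, indexed like predictions by slide_id) adds
    human readers to the agreement matrix alongside the gold standard and
    the model.
    """
    for col in ("predicted_label", "true_label", "slide_score"):
        if col not in predictions.columns:
            raise ValueError(f"predictions table missing column {col!r}")
    conf = confusion_metrics(predictions["predicted_label"], predictions["true_label"])
    roc = None
    if predictions["true_label"].nunique() == 2:
        roc = roc_auc(predictions["slide_score"], predictions["true_label"], n_boot=n_boot, seed=seed)
    reads = pd.DataFrame(
        {"gold_standard": predictions["true_label"].to_numpy(), "model": predictions["predicted_label"].to_numpy()},
        index=predictions["slide_id"],
    )
    if extra_raters is not None:
        reads = reads.join(extra_raters)
    agreement = kendall_tau_matrix(reads)
    return DiagnosticReport(confusion=conf, roc=roc, agreement=agreement)


def plot_roc(roc: RocResult, ax=None):
    """ROC curve with the AUC in the legend (matplotlib Axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    fpr = [p[0] for p in roc.curve]
    tpr = [p[1] for p in roc.curve]
    ax.plot(fpr, tpr, label=f"AUC = {roc.auc:.4f} (95% CI {roc.ci_low:.4f}-{roc.ci_high:.4f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax
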