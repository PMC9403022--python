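"""Tissue-ratio quantification and segmentation evaluation metrics.

Ratios: for valid patch i, let E_i, S_i be the epithelial and stromal pixel
counts and T_i = E_i + S_i the tissue count; then
``ratio_epi = sum E_i / sum T_i`` and ``ratio_stro = sum S_i / sum T_i``.
Defining T_i as E_i + S_i (model-predicted tissue rather than the clustering
foreground) makes the two ratios sum to exactly 1 whenever any tissue is
present.

Evaluation: the ten standard confusion-matrix metrics (TPR, TNR, PPV, NPV,
FPR, FDR, FNR, ACC, F1, MCC).  Values are kept at full precision on the unit
scale; the x100 / 2-decimal formatting happens only in reporting helpers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatchTissueCounts",
    "TissueRatios",
    "ConfusionCounts",
    "MetricSet",
    "count_patch",
    "compute_ratios",
    "confusion",
    "compute_metrics",
    "metrics_from_rates",
    "macro_average",
]

METRIC_NAMES = ("TPR", "TNR", "PPV", "NPV", "FPR", "FDR", "FNR", "ACC", "F1", "MCC")


@dataclass(frozen=True)
class PatchTissueCounts:
    """Pixel counts of one valid patch: tissue (T), epithelium (E), stroma (S)."""

    tissue: int
    epithelium: int
    stroma: int

    def __post_init__(self):
        if min(self.tissue, self.epithelium, self.stroma) < 0:
            raise ValueError("counts must be non-negative")
        if self.tissue != self.epithelium + self.stroma:
            raise ValueError("tissue count must equal epithelium + stroma")


@dataclass(frozen=True)
class TissueRatios:
    ratio_epi: float
    ratio_stro: float


@dataclass(frozen=True)
class ConfusionCounts:
    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The ten metrics on the unit scale (NaN where a denominator is zero)."""

    TPR: float
    TNR: float
    PPV: float
    NPV: float
    FPR: float
    FDR: float
    FNR: float
    ACC: float
    F1: float
    MCC: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}

    def as_percent(self, decimals: int = 2) -> dict[str, float]:
        """Reporting form: x100 rounded; MCC is conventionally also x100."""
        return {k: round(100.0 * v, decimals) for k, v in self.as_dict().items()}

    def summary(self) -> str:
        pct = self.as_percent()
        head = "  ".join(f"{k:>6}" for k in METRIC_NAMES)
        vals = "  ".join(f"{pct[k]:6.2f}" for k in METRIC_NAMES)
        return head + "\n" + vals


def count_patch(mask: np.ndarray) -> PatchTissueCounts:
    """Count labelled pixels in a 0/1/2 tissue mask."""
    mask = np.asarray(mask)
    e = int(np.count_nonzero(mask == 1))
    s = int(np.count_nonzero(mask == 2))
    return PatchTissueCounts(tissue=e + s, epithelium=e, stroma=s)


def compute_ratios(counts: list[PatchTissueCounts]) -> TissueRatios:
    """Pooled epithelial / stromal area ratios over the valid patches."""
    t = sum(c.tissue for c in counts)
    if t == 0:
        raise ValueError("no tissue: ratio undefined")
    e = sum(c.epithelium for c in counts)
    s = sum(c.stroma for c in counts)
    return TissueRatios(ratio_epi=e / t, ratio_stro=s / t)


def confusion(
    pred: np.ndarray,
    truth: np.ndarray,
    positive_label: int,
    ignore_label: int = 0,
) -> ConfusionCounts:
    """Binary confusion counts over pixels whose truth label is not ignored.

    ``positive_label`` is treated as positive; every other (non-ignored)
    truth label is negative.  Predictions equal to ``positive_label`` count
    as positive calls; everything else (including predicted background)
    counts as a negative call.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch between prediction and truth")
    keep = truth != ignore_label
    p_pos = pred[keep] == positive_label
    t_pos = truth[keep] == positive_label
    tp = int(np.count_nonzero(p_pos & t_pos))
    fp = int(np.count_nonzero(p_pos & ~t_pos))
    fn = int(np.count_nonzero(~p_pos & t_pos))
    tn = int(np.count_nonzero(~p_pos & ~t_pos))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined: zero denominator")
        return float("nan")
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The ten confusion-matrix metrics, exactly as conventionally defined:

    TPR = TP/(TP+FN); TNR = TN/(FP+TN); PPV = TP/(TP+FP); NPV = TN/(FN+TN);
    FPR = FP/(FP+TN); FDR = 1 - PPV; FNR = FN/(FN+TP);
    ACC = (TP+TN)/total; F1 = 2TP/(2TP+FP+FN);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    tpr = _ratio(tp, tp + fn, "TPR")
    tnr = _ratio(tn, fp + tn, "TNR")
    ppv = _ratio(tp, tp + fp, "PPV")
    npv = _ratio(tn, fn + tn, "NPV")
    fpr = _ratio(fp, fp + tn, "FPR")
    fdr = _ratio(fp, tp + fp, "FDR")
    fnr = _ratio(fn, fn + tp, "FNR")
    acc = _ratio(tp + tn, c.total, "ACC")
    f1 = _ratio(2 * tp, 2 * tp + fp + fn, "F1")
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        warnings.warn("MCC undefined: zero denominator")
        mcc = float("nan")
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den)
    return MetricSet(TPR=tpr, TNR=tnr, PPV=ppv, NPV=npv, FPR=fpr, FDR=fdr, FNR=fnr, ACC=acc, F1=f1, MCC=mcc)


def metrics_from_rates(tpr: float, tnr: float, ppv: float) -> MetricSet:
    """Recover the full metric set from three summary rates.

    The class prevalence p is the unique solution (for a unit total) of the
    PPV identity PPV = TPR*p / (TPR*p + (1-TNR)*(1-p)); the implied
    fractional confusion counts then yield every other metric.  Useful for
    internal-consistency checks of published evaluation tables that print
    rates but not raw counts.
    """
    if not (0 < tpr <= 1 and 0 < tnr <= 1 and 0 < ppv <= 1):
        raise ValueError("rates must lie in (0, 1]")
    fpr = 1.0 - tnr
    p = ppv * fpr / (tpr * (1.0 - ppv) + ppv * fpr) if tpr * (1.0 - ppv) + ppv * fpr > 0 else 1.0
    c = ConfusionCounts(tp=tpr * p, fn=(1 - tpr) * p, tn=tnr * (1 - p), fp=fpr * (1 - p))
    return compute_metrics(c)


def macro_average(sets: list[MetricSet]) -> MetricSet:
    """Unweighted mean of per-image metric sets (the pooled-count form is the
    default elsewhere; this is the macro-averaged alternative)."""
    if not sets:
        raise ValueError("empty metric list")
    vals = {k: float(np.mean([getattr(m, k) for m in sets])) for k in METRIC_NAMES}
    return MetricSet(**vals)
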