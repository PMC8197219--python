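"""Per-voxel confusion statistics and ROC/AUC.

Evaluation is restricted to an explicit region (by default the voxels
within 6 Å of any protein atom) so that bulk vacuum far from the protein,
which is trivially non-binding, does not inflate specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["MetricsReport", "compute_metrics", "roc_auc", "report_table"]


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    mcc: float
    auc: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "mcc": self.mcc, "auc": self.auc,
        }


def _ratio(num: float, den: float) -> float:
    return float(num / den) if den else 0.0


def compute_metrics(pred_binary, mask, eval_region=None, heat=None) -> MetricsReport:
    """Confusion counts and derived statistics over the evaluation region.

    MCC uses the convention that a zero factor in the denominator yields 0.
    If a heat map is supplied, AUC is computed over the same region.
    """
    p = np.asarray(getattr(pred_binary, "values", pred_binary)).astype(bool)
    y = np.asarray(getattr(mask, "values", mask)).astype(bool)
    if p.shape != y.shape:
        raise ValueError(f"prediction {p.shape} vs mask {y.shape}")
    if eval_region is None:
        region = np.ones(p.shape, dtype=bool)
    else:
        region = np.asarray(eval_region).astype(bool)
        if region.shape != p.shape:
            raise ValueError(f"eval region {region.shape} vs arrays {p.shape}")
        if not region.any():
            raise ValueError("evaluation region is empty")
    pr, yr = p[region], y[region]
    tp = int(np.sum(pr & yr))
    fp = int(np.sum(pr & ~yr))
    tn = int(np.sum(~pr & ~yr))
    fn = int(np.sum(~pr & yr))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    auc = float("nan")
    if heat is not None:
        auc = roc_auc(heat, y, region)
    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=_ratio(tp + tn, tp + fp + tn + fn),
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        precision=_ratio(tp, tp + fp),
        mcc=float(mcc),
        auc=auc,
    )


def roc_auc(heat, mask, eval_region=None) -> float:
    """Area under the ROC curve via the midrank (Mann–Whitney) statistic."""
    h = np.asarray(getattr(heat, "values", heat), dtype=float)
    y = np.asarray(getattr(mask, "values", mask)).astype(bool)
    if h.shape != y.shape:
        raise ValueError(f"heat map {h.shape} vs mask {y.shape}")
    if eval_region is not None:
        region = np.asarray(eval_region).astype(bool)
        h, y = h[region], y[region]
    h, y = h.ravel(), y.ravel()
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUC undefined: evaluation region contains a single class")
        return float("nan")
    ranks = rankdata(h)  # midranks for ties
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def report_table(reports: dict[str, MetricsReport]) -> pd.DataFrame:
    """One row per complex plus micro (pooled counts) and macro (mean) rows."""
    rows = {k: r.as_dict() for k, r in reports.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if rows:
        tp, fp = int(df.tp.sum()), int(df.fp.sum())
        tn, fn = int(df.tn.sum()), int(df.fn.sum())
        pooled = compute_metrics(
            np.repeat([True, True, False, False], [tp, fp, tn, fn]),
            np.repeat([True, False, False, True], [tp, fp, tn, fn]),
        )
        micro = pooled.as_dict()
        micro["auc"] = float("nan")
        macro = df.mean(numeric_only=True).to_dict()
        df.loc["micro"] = micro
        df.loc["macro"] = macro
    return df
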