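"""Voxel-wise evaluation of automatic vs. reference (manual) segmentation.

For each reference node (class) the automatic mask is scored with five
voxel-wise metrics over the full field of view:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)          (positive predictive value)
    recall    = TP / (TP + FN)          (sensitivity)
    dice      = 2 TP / (2 TP + FP + FN) (F1 score)
    jaccard   = TP / (TP + FP + FN)     (intersection over union)

with the identities dice = 2PR/(P+R) and dice = 2J/(1+J) holding exactly.
Aggregates follow the usual multi-class semantics: micro pools confusion
counts across classes, macro averages classes with equal weight, weighted
averages by class support (reference voxel count). Because the nodal target
volume is tiny relative to the scanned field of view, accuracy is inflated by
class imbalance — Dice/Jaccard are the realistic overlap summaries.

Undefined quotients (0/0, e.g. precision with no predicted voxels) are
reported as absent (NaN), never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import LabelMask

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "METRIC_NAMES",
    "match_components",
    "confusion",
    "class_metrics",
    "aggregate",
    "aggregate_metrics",
    "evaluate",
]

METRIC_NAMES = ("precision", "recall", "dice", "jaccard", "accuracy")


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-wise confusion counts for one binary class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def support(self) -> int:
        """Reference (truth) voxel count for the class."""
        return self.tp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def class_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """The five voxel-wise metrics; 0/0 quotients come back as NaN (absent)."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    return {
        "precision": _ratio(tp, tp + fp),
        "recall": _ratio(tp, tp + fn),
        "dice": _ratio(2 * tp, 2 * tp + fp + fn) if (tp + fp + fn) > 0 else float("nan"),
        "jaccard": _ratio(tp, tp + fp + fn),
        "accuracy": _ratio(tp + tn, counts.total),
    }


def confusion(pred: LabelMask | np.ndarray, truth: LabelMask | np.ndarray) -> ConfusionCounts:
    """Voxel-wise confusion counts between two aligned binary masks."""
    p, t = _aligned_bool(pred, truth)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _aligned_bool(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pred, LabelMask) and isinstance(truth, LabelMask):
        if not pred.geometry.isclose(truth.geometry, tol=1e-6):
            raise ValueError(f"mask geometries differ: {pred.geometry} vs {truth.geometry}")
        return pred.as_bool(), truth.as_bool()
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: {p.shape} vs {t.shape}")
    return p, t


def aggregate(
    counts: list[ConfusionCounts],
    mode: str,
    supports: list[int] | None = None,
) -> dict[str, float]:
    """Aggregate per-class confusion counts into one metric tuple.

    ``micro`` pools the counts and applies the formulas once; ``macro`` is the
    unweighted mean of per-class metrics; ``weighted`` is the support-weighted
    mean (support defaults to each class's truth voxel count). Absent (NaN)
    per-class values are excluded from macro/weighted means.
    """
    if not counts:
        raise ValueError("aggregate requires at least one class")
    if mode == "micro":
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        return class_metrics(pooled)
    if mode not in ("macro", "weighted"):
        raise ValueError(f"unknown aggregation mode {mode!r}; use micro, macro or weighted")
    if supports is None:
        supports = [c.support for c in counts]
    if len(supports) != len(counts):
        raise ValueError("supports and counts must have equal length")
    per = [class_metrics(c) for c in counts]
    out: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.array([m[name] for m in per], dtype=float)
        w = np.ones(len(vals)) if mode == "macro" else np.asarray(supports, dtype=float)
        ok = ~np.isnan(vals)
        out[name] = float(np.average(vals[ok], weights=w[ok])) if ok.any() and w[ok].sum() > 0 else float("nan")
    return out


def aggregate_metrics(per_class_metrics: list[dict[str, float]], supports: list[int] | None = None,
                      mode: str = "macro") -> dict[str, float]:
    """Macro/weighted averaging directly on already-computed metric tuples.

    Useful when only reported per-class metric values (not confusion counts)
    are available, e.g. to recompute a results table's average rows.
    """
    if not per_class_metrics:
        raise ValueError("need at least one class")
    if mode == "micro":
        raise ValueError("micro aggregation needs confusion counts, not metric tuples")
    if supports is None:
        if mode == "weighted":
            raise ValueError("weighted aggregation needs supports")
        supports = [1] * len(per_class_metrics)
    keys = per_class_metrics[0].keys()
    out = {}
    for name in keys:
        vals = np.array([m[name] for m in per_class_metrics], dtype=float)
        w = np.ones(len(vals)) if mode == "macro" else np.asarray(supports, dtype=float)
        ok = ~np.isnan(vals)
        out[name] = float(np.average(vals[ok], weights=w[ok])) if ok.any() else float("nan")
    return out


def match_components(pred: LabelMask, truth: LabelMask) -> dict[int, int | None]:
    """Map each predicted component to the truth label it overlaps most.

    Ties go to the lower truth label; components with zero overlap map to
    ``None`` (they will be counted as false positives).
    """
    if not pred.geometry.isclose(truth.geometry, tol=1e-6):
        raise ValueError(f"mask geometries differ: {pred.geometry} vs {truth.geometry}")
    mapping: dict[int, int | None] = {}
    pl = pred.labels
    tl = truth.labels
    n_t = int(tl.max(initial=0))
    for lab in sorted(pred.label_set - {0}):
        overlap = np.bincount(tl[pl == lab], minlength=n_t + 1)
        overlap[0] = 0
        best = int(overlap.argmax())  # argmax breaks ties toward the lower label
        mapping[lab] = best if overlap[best] > 0 else None
    return mapping


@dataclass(frozen=True)
class MetricsReport:
    """Per-class confusion counts + metrics, and micro/macro/weighted aggregates."""

    per_class: dict[int, ConfusionCounts]
    class_names: dict[int, str] = field(default_factory=dict)
    unmatched_fp: int = 0
    total_voxels: int = 0

    def metrics(self, label: int) -> dict[str, float]:
        return class_metrics(self.per_class[label])

    def support(self, label: int) -> int:
        return self.per_class[label].support

    def aggregate(self, mode: str) -> dict[str, float]:
        counts = [self.per_class[k] for k in sorted(self.per_class)]
        if mode == "micro" and self.unmatched_fp > 0:
            # predicted components matching no reference node enter the pooled
            # counts once, as pure false positives
            pool = ConfusionCounts(
                tp=0, fp=self.unmatched_fp, fn=0, tn=self.total_voxels - self.unmatched_fp
            )
            counts = counts + [pool]
        return aggregate(counts, mode)

    def to_frame(self) -> pd.DataFrame:
        """Per-class rows followed by micro/macro/weighted average rows."""
        rows = []
        for lab in sorted(self.per_class):
            m = self.metrics(lab)
            rows.append(
                {"class": self.class_names.get(lab, f"node_{lab}"), "support": self.support(lab), **m}
            )
        for mode in ("micro", "macro", "weighted"):
            rows.append({"class": f"{mode} average", "support": sum(self.support(k) for k in self.per_class),
                         **self.aggregate(mode)})
        return pd.DataFrame(rows, columns=["class", "support", *METRIC_NAMES])


def evaluate(pred: LabelMask, truth: LabelMask) -> MetricsReport:
    """Full evaluation of a predicted component mask against a reference mask.

    Predicted components are first attributed to reference nodes by maximal
    overlap; each reference class is then scored voxel-wise over the full
    field of view against the union of its matched components. Predicted
    components matching no reference node contribute false positives to the
    pooled (micro) counts via a dedicated unmatched pool.
    """
    mapping = match_components(pred, truth)
    truth_labels = sorted(truth.label_set - {0})
    if not truth_labels:
        raise ValueError("reference mask contains no labeled nodes")
    per_class: dict[int, ConfusionCounts] = {}
    pl = pred.labels
    for t_lab in truth_labels:
        matched = [p for p, t in mapping.items() if t == t_lab]
        pred_bin = np.isin(pl, matched) if matched else np.zeros_like(pl, dtype=bool)
        per_class[t_lab] = confusion(pred_bin, truth.labels == t_lab)
    unmatched = [p for p, t in mapping.items() if t is None]
    unmatched_fp = int(np.count_nonzero(np.isin(pl, unmatched))) if unmatched else 0
    return MetricsReport(
        per_class=per_class,
        unmatched_fp=unmatched_fp,
        total_voxels=int(pl.size),
    )
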