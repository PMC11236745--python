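"""Segmentation metrics: accuracy, IoU, Dice, sensitivity, specificity.

Metrics are computed per image from one-vs-rest confusion counts and then
averaged (the pooled alternative — summing counts over images first — is
available by flag).  Multi-class reports list every foreground class plus
their unweighted average; the background class is excluded from averages.
Repeated-run reports carry mean and sample standard deviation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np

from .training import predict

__all__ = ["ConfusionCounts", "confusion", "metric_suite", "evaluate",
           "report_to_json", "report_to_csv"]

METRIC_NAMES = ("acc", "iou", "dice", "sens", "spec")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __add__(self, other):
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )

    @property
    def total(self):
        return self.tp + self.fp + self.tn + self.fn


def confusion(pred_labels, truth_labels, class_id) -> ConfusionCounts:
    """One-vs-rest pixel counts for ``class_id``."""
    pred = np.asarray(pred_labels)
    truth = np.asarray(truth_labels)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    p = pred == class_id
    t = truth == class_id
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _safe(num, den, neutral):
    return num / den if den > 0 else neutral


def metric_suite(c: ConfusionCounts) -> dict:
    """The five reported scores from one set of counts.

    When a denominator is zero the score is 1 if the class is absent from
    both prediction and truth (vacuously perfect), else 0.
    """
    absent = (c.tp + c.fn == 0) and (c.tp + c.fp == 0)
    neutral = 1.0 if absent else 0.0
    return {
        "acc": _safe(c.tp + c.tn, c.total, neutral),
        "iou": _safe(c.tp, c.tp + c.fp + c.fn, neutral),
        "dice": _safe(2 * c.tp, 2 * c.tp + c.fp + c.fn, neutral),
        "sens": _safe(c.tp, c.tp + c.fn, neutral),
        "spec": _safe(c.tn, c.tn + c.fp, 1.0 if c.tn + c.fp == 0 else 0.0),
    }


def _single_run(model, samples, foreground, aggregate):
    """Per-class metric means over samples for one model."""
    per_class = {cid: [] for cid in foreground}
    pooled = {cid: ConfusionCounts(0, 0, 0, 0) for cid in foreground}
    for s in samples:
        image = s.image if hasattr(s, "image") else s[0]
        mask = s.mask if hasattr(s, "mask") else s[1]
        _, labels = predict(model, image)
        for cid in foreground:
            cc = confusion(labels, mask, cid)
            per_class[cid].append(metric_suite(cc))
            pooled[cid] = pooled[cid] + cc
    out = {}
    for cid in foreground:
        if aggregate == "pooled":
            out[cid] = metric_suite(pooled[cid])
        else:
            out[cid] = {
                m: float(np.mean([r[m] for r in per_class[cid]]))
                for m in METRIC_NAMES
            }
    return out


def evaluate(model, samples, n_runs=1, aggregate="image", class_names=None):
    """Per-class and average metric report, optionally over repeated runs.

    ``model`` is a trained network, a list of networks (one per run), or a
    callable ``run_index -> network``.  With ``n_runs > 1`` the report
    carries mean and sample standard deviation across runs; with one run the
    std fields are omitted.
    """
    if len(samples) == 0:
        raise ValueError("no samples to evaluate")
    first = samples[0]
    mask0 = first.mask if hasattr(first, "mask") else first[1]
    names = class_names or getattr(first, "class_names", None)
    n_classes = max(int(np.max(mask0)) + 1, 2)
    foreground = list(range(1, n_classes))

    def model_for(i):
        if callable(model) and not hasattr(model, "forward_all"):
            return model(i)
        if isinstance(model, (list, tuple)):
            return model[i]
        return model

    runs = [
        _single_run(model_for(i), samples, foreground, aggregate)
        for i in range(n_runs)
    ]

    def summarize(values):
        rec = {"mean": float(np.mean(values))}
        if n_runs > 1:
            rec["std"] = float(np.std(values, ddof=1))
        return rec

    report = {"n_runs": n_runs, "aggregate": aggregate, "per_class": {}}
    for cid in foreground:
        label = (
            names[cid] if names and cid < len(names) else f"class{cid}"
        )
        report["per_class"][label] = {
            m: summarize([run[cid][m] for run in runs]) for m in METRIC_NAMES
        }
    report["average"] = {
        m: summarize(
            [
                np.mean([run[cid][m] for cid in foreground])
                for run in runs
            ]
        )
        for m in METRIC_NAMES
    }
    return report


def report_to_json(report, path):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)


def report_to_csv(report, path):
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["class", "metric", "mean", "std"])
        rows = list(report["per_class"].items()) + [("average", report["average"])]
        for label, metrics in rows:
            for m, rec in metrics.items():
                writer.writerow([label, m, rec["mean"], rec.get("std", "")])
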