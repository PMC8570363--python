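"""Clustering and feature-selection accuracy metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

__all__ = ["MetricReport", "adjusted_rand_index", "feature_f1", "report"]


@dataclass
class MetricReport:
    ari: float
    f1_per_view: list[float]
    f1_overall: float
    precision: list[float]
    recall: list[float]


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    1 for identical partitions up to relabeling, ~0 for random agreement.
    """
    labels_a = np.asarray(labels_a).reshape(-1)
    labels_b = np.asarray(labels_b).reshape(-1)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors must have equal length")
    if len(labels_a) < 2:
        raise ValueError("need at least two samples")
    return float(adjusted_rand_score(labels_a, labels_b))


def _prec_recall(selected: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    selected = np.asarray(selected, dtype=bool).reshape(-1)
    truth = np.asarray(truth, dtype=bool).reshape(-1)
    if selected.shape != truth.shape:
        raise ValueError("masks must have equal length")
    if not truth.any():
        raise ValueError("truth mask has no positive features (metric undefined)")
    tp = int((selected & truth).sum())
    prec = tp / selected.sum() if selected.any() else 0.0
    rec = tp / truth.sum()
    return prec, rec


def feature_f1(selected, truth) -> float:
    """F1 = 2PR/(P+R) of a selected-feature mask against the truth; 0 when
    nothing is selected.  Multi-view masks (lists) are pooled first."""
    if isinstance(selected, (list, tuple)):
        selected = np.concatenate([np.asarray(m, bool) for m in selected])
        truth = np.concatenate([np.asarray(m, bool) for m in truth])
    prec, rec = _prec_recall(selected, truth)
    if prec + rec == 0:
        return 0.0
    return 2.0 * prec * rec / (prec + rec)


def report(labels_true, labels_est, selected=None, truth=None) -> MetricReport:
    """Bundle ARI plus per-view and pooled feature F1."""
    ari = adjusted_rand_index(labels_true, labels_est)
    if selected is None:
        return MetricReport(ari, [], float("nan"), [], [])
    f1s, precs, recs = [], [], []
    for sel, tru in zip(selected, truth):
        p, r = _prec_recall(sel, tru)
        precs.append(p)
        recs.append(r)
        f1s.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
    return MetricReport(
        ari=ari,
        f1_per_view=f1s,
        f1_overall=feature_f1(list(selected), list(truth)),
        precision=precs,
        recall=recs,
    )
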