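"""Evaluation metrics for imbalanced per-residue binary classification.

Threshold-dependent scalars (specificity, precision, recall, F1, MCC) are
computed from pooled confusion counts; any metric whose denominator is zero is
reported as 0 (and MCC is 0 whenever a factor under the root vanishes), so
reports are always total.  Threshold-free evaluation uses the ROC curve with
trapezoidal AUC — which equals the Mann-Whitney pairwise concordance
probability with ties counted one half — and the precision-recall curve with
step-interpolated area (AUPR), the conservative convention for rare-positive
tasks.

The module also provides amino-acid composition distributions over selected
residues and the (smoothed) Kullback-Leibler divergence between two such
distributions, used to compare the composition of predicted binding sites
with annotated ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .backbone import PredictionTrack
from .seqio import LabelTrack

#: the 20 canonical amino acids (composition distributions exclude 'X')
CANONICAL_AAS = "ACDEFGHIKLMNPQRSTVWY"

KL_SMOOTHING = 1e-10


class MetricsError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise MetricsError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ScalarMetrics:
    spe: float
    pre: float
    rec: float
    f1: float
    mcc: float


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    scalars: ScalarMetrics
    roc: np.ndarray  # (n, 2) columns (fpr, tpr)
    pr: np.ndarray  # (n, 2) columns (recall, precision)
    auc: float
    aupr: float


def _pool(
    preds: Sequence[PredictionTrack], truth: Sequence[LabelTrack]
) -> tuple[np.ndarray, np.ndarray]:
    by_id = {t.id: t for t in truth}
    scores, labels = [], []
    for p in preds:
        if p.id not in by_id:
            raise MetricsError(f"no label track for prediction id {p.id!r}")
        t = by_id[p.id]
        if len(p) != len(t):
            raise MetricsError(
                f"id {p.id!r}: prediction length {len(p)} != label length {len(t)}"
            )
        scores.append(p.p_bind)
        labels.append(np.asarray(t.labels))
    return np.concatenate(scores), np.concatenate(labels)


def confusion(
    preds: Sequence[PredictionTrack],
    truth: Sequence[LabelTrack],
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Pooled confusion counts over all residues of all sequences."""
    scores, labels = _pool(preds, truth)
    calls = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(calls & pos)),
        fp=int(np.sum(calls & ~pos)),
        tn=int(np.sum(~calls & ~pos)),
        fn=int(np.sum(~calls & pos)),
    )


def scalar_metrics(c: ConfusionCounts) -> ScalarMetrics:
    """Specificity, precision, recall, F1 and MCC from confusion counts."""

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    tp, fp, tn, fn = (float(v) for v in (c.tp, c.fp, c.tn, c.fn))
    spe = ratio(tn, tn + fp)
    pre = ratio(tp, tp + fp)
    rec = ratio(tp, tp + fn)
    f1 = ratio(2.0 * pre * rec, pre + rec)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / np.sqrt(denom2) if denom2 > 0 else 0.0
    return ScalarMetrics(spe, pre, rec, f1, float(mcc))


def roc_pr_curves(
    scores: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """ROC and PR curves with trapezoidal AUC and step-interpolated AUPR."""
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel()
    if scores.shape != truth.shape:
        raise MetricsError("scores and truth must have the same length")
    n_pos = int(np.sum(truth == 1))
    if n_pos == 0 or n_pos == truth.size:
        raise MetricsError("ROC/PR need at least one positive and one negative residue")
    fpr, tpr, _ = roc_curve(truth, scores)
    auc = float(np.trapezoid(tpr, fpr))
    precision, recall, _ = precision_recall_curve(truth, scores)
    aupr = float(average_precision_score(truth, scores))
    roc = np.column_stack([fpr, tpr])
    pr = np.column_stack([recall[::-1], precision[::-1]])
    return roc, pr, auc, aupr


def evaluate(
    preds: Sequence[PredictionTrack],
    truth: Sequence[LabelTrack],
    threshold: float = 0.5,
) -> MetricsReport:
    """Full report: confusion at the threshold plus threshold-free curves."""
    c = confusion(preds, truth, threshold)
    scores, labels = _pool(preds, truth)
    roc, pr, auc, aupr = roc_pr_curves(scores, labels)
    return MetricsReport(c, scalar_metrics(c), roc, pr, auc, aupr)


def composition(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    selections: Mapping[str, np.ndarray] | Iterable[tuple[str, np.ndarray]] | None = None,
) -> dict[str, float]:
    """Amino-acid frequency distribution over selected residues.

    ``sequences`` maps id -> sequence; ``selections`` maps id -> boolean/0-1
    vector picking the residues to tally (default: all).  'X' residues are
    excluded from the tally; frequencies are over the 20 canonical letters and
    sum to 1.
    """
    seqs = dict(sequences)
    sel = dict(selections) if selections is not None else None
    counts = {aa: 0 for aa in CANONICAL_AAS}
    for rid, seq in seqs.items():
        pick = np.ones(len(seq), dtype=bool) if sel is None else np.asarray(sel[rid], dtype=bool)
        if pick.shape[0] != len(seq):
            raise MetricsError(f"id {rid!r}: selection length != sequence length")
        for ch, keep in zip(seq, pick):
            if keep and ch in counts:
                counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise MetricsError("selection contains no canonical residues")
    return {aa: counts[aa] / total for aa in CANONICAL_AAS}


def kl_divergence(
    p: Mapping[str, float] | Sequence[float],
    q: Mapping[str, float] | Sequence[float],
    smoothing: float = KL_SMOOTHING,
) -> float:
    """KL(p || q) in nats, with additive smoothing on both distributions.

    Both inputs must be non-negative and sum to ~1; asymmetric by design
    (compute both directions to report forward and reverse divergence).
    """

    def to_vec(d) -> np.ndarray:
        if isinstance(d, Mapping):
            keys = sorted(d)
            return np.array([d[k] for k in keys], dtype=float)
        return np.asarray(d, dtype=float)

    pv, qv = to_vec(p), to_vec(q)
    if isinstance(p, Mapping) and isinstance(q, Mapping) and sorted(p) != sorted(q):
        raise MetricsError("distributions are over different categories")
    if pv.shape != qv.shape:
        raise MetricsError("distributions must have the same number of categories")
    if np.any(pv < 0) or np.any(qv < 0):
        raise MetricsError("distributions must be non-negative")
    if not (np.isclose(pv.sum(), 1.0, atol=1e-6) and np.isclose(qv.sum(), 1.0, atol=1e-6)):
        raise MetricsError("distributions must sum to 1")
    pv = (pv + smoothing) / (pv + smoothing).sum()
    qv = (qv + smoothing) / (qv + smoothing).sum()
    return float(np.sum(pv * np.log(pv / qv)))
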