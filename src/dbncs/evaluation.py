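"""Confusion counts, classification metrics and ROC/AUC versus a gold standard.

The evaluation universe is the N(N-1) ordered non-self gene pairs (this is
the convention under which the printed benchmark rows are self-consistent);
undirected evaluation collapses both networks to unordered pairs first,
giving a universe of N(N-1)/2.

    TPR = TP/(TP+FN)        FPR = FP/(FP+TN)
    PPV = TP/(TP+FP)        ACC = (TP+TN)/total
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric with a zero denominator is reported as NaN (undefined), never as
0. AUC is the rank statistic over candidate-edge scores with ties averaged;
pairs without a score (e.g. removed during skeleton learning) count as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .io_formats import Network

__all__ = ["ConfusionCounts", "MetricReport", "confusion_counts", "classification_metrics", "roc_auc"]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    tpr: float
    fpr: float
    ppv: float
    acc: float
    mcc: float
    auc: float | None = None

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        out = {
            "tpr": self.tpr,
            "fpr": self.fpr,
            "ppv": self.ppv,
            "acc": self.acc,
            "mcc": self.mcc,
        }
        if self.auc is not None:
            out["auc"] = self.auc
        return {k: round(v, ndigits) for k, v in out.items()}


def _pair_universe(gene_ids: list[str], directed: bool):
    if directed:
        return {
            (u, v) for u in gene_ids for v in gene_ids if u != v
        }
    return {frozenset((u, v)) for u in gene_ids for v in gene_ids if u != v}


def confusion_counts(pred: Network, gold: Network, directed: bool = True) -> ConfusionCounts:
    """Count TP/FP/TN/FN of a predicted network against the gold standard."""
    if set(pred.gene_ids) != set(gold.gene_ids):
        missing = sorted(set(gold.gene_ids) ^ set(pred.gene_ids))
        raise ValueError(f"gene universes differ; mismatched ids: {missing}")
    universe = _pair_universe(gold.gene_ids, directed)
    if directed:
        p, g = set(pred.edges), set(gold.edges)
    else:
        p = {frozenset(e) for e in pred.edges}
        g = {frozenset(e) for e in gold.edges}
    tp = len(p & g)
    fp = len(p - g)
    fn = len(g - p)
    tn = len(universe) - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float) -> float:
    return num / den if den else math.nan


def classification_metrics(c: ConfusionCounts) -> MetricReport:
    """The metric vector from the counts; zero denominators give NaN."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    mcc_den = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return MetricReport(
        tpr=_ratio(tp, tp + fn),
        fpr=_ratio(fp, fp + tn),
        ppv=_ratio(tp, tp + fp),
        acc=_ratio(tp + tn, c.total),
        mcc=(tp * tn - fp * fn) / mcc_den if mcc_den else math.nan,
    )


def roc_auc(scores: dict[tuple[str, str], float], gold: Network) -> float:
    """AUC of candidate-edge scores against the gold standard (directed).

    The score map may cover any subset of the N(N-1) ordered pairs; missing
    pairs score 0. Invariant under strictly monotone score transforms.
    """
    genes = gold.gene_ids
    pairs = [(u, v) for u in genes for v in genes if u != v]
    y = np.array([1 if p in gold.edges else 0 for p in pairs])
    s = np.array([scores.get(p, 0.0) for p in pairs], dtype=float)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("AUC undefined: gold has zero positives or zero negatives")
    return float(roc_auc_score(y, s))
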