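"""Score ranked association output against simulation ground truth.

A reported marker is a true positive when its dosage vector has squared
Pearson correlation r^2 >= a threshold (default 0.8) with at least one
hidden causal variant; it is attributed to its best-correlated causal
locus.  The true-positive count is the number of *distinct* causal loci
tagged by any TP hit, so several tags of one locus count once.  False
positive hits are greedily clustered: the most significant unclustered
FP absorbs all FP hits within +-50 kb, and the FP count is the number
of clusters — a run of correlated false hits in one LD block counts as
a single false discovery.

Power at a fixed FDR walks the ranked list, computing at each prefix
FDR = FP clusters / (FP clusters + TP loci) and recall = TP loci / m,
and reports the maximum recall over prefixes meeting the FDR target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeDataset
from .simulate import SimulationTruth

DEFAULT_R2_THRESHOLD = 0.8
FP_CLUSTER_RADIUS_BP = 50_000


@dataclass
class EvaluationResult:
    """Power at the FDR target plus the full precision-recall walk."""

    power: float
    fdr_target: float
    tp_count: int                 # distinct causal loci tagged in the full list
    fp_clusters: int              # false-positive clusters in the full list
    curve: pd.DataFrame           # per-prefix recall / precision / fdr

    def __post_init__(self):
        assert 0.0 <= self.power <= 1.0


def classify_hits(hits: pd.DataFrame, truth: SimulationTruth,
                  g: GenotypeDataset,
                  r2_threshold: float = DEFAULT_R2_THRESHOLD) -> pd.DataFrame:
    """Label ranked hits as TP/FP by max r^2 against the causal dosages.

    ``hits`` needs columns (id, p); rows must be sorted by significance.
    Returns the table with added columns r2 (best causal r^2), causal
    (the best locus index, -1 for FP), tp (bool), plus chrom/bp pulled
    from the dataset.
    """
    if truth.causal_dosages is None:
        raise ValueError("truth carries no causal dosages to correlate against")
    idx = g.marker_index(hits["id"])
    X = g.dosages[:, idx]
    Ccaus = truth.causal_dosages
    Xc = X - X.mean(axis=0)
    Cc = Ccaus - Ccaus.mean(axis=0)
    denom = np.sqrt(np.einsum("ij,ij->j", Xc, Xc)[:, None]
                    * np.einsum("ij,ij->j", Cc, Cc)[None, :])
    denom[denom == 0] = np.inf
    r2 = (Xc.T @ Cc / denom) ** 2
    best = r2.argmax(axis=1)
    best_r2 = r2[np.arange(len(idx)), best]
    out = hits.reset_index(drop=True).copy()
    out["chrom"] = g.markers["chrom"].to_numpy()[idx]
    out["bp"] = g.markers["bp"].to_numpy()[idx]
    out["r2"] = best_r2
    out["tp"] = best_r2 >= r2_threshold
    out["causal"] = np.where(out["tp"], best, -1)
    return out


def count_tp_fp(labels: pd.DataFrame) -> tuple[int, int]:
    """(distinct causal loci tagged, greedy 100-kb FP cluster count)."""
    tp_count = labels.loc[labels["tp"], "causal"].nunique()
    fp = labels[~labels["tp"]].sort_values("p", kind="stable")
    clustered = np.zeros(len(fp), dtype=bool)
    chrom = fp["chrom"].to_numpy()
    bp = fp["bp"].to_numpy()
    n_clusters = 0
    for i in range(len(fp)):
        if clustered[i]:
            continue
        n_clusters += 1
        member = (chrom == chrom[i]) & (np.abs(bp - bp[i]) <= FP_CLUSTER_RADIUS_BP)
        clustered |= member
    return int(tp_count), int(n_clusters)


def power_at_fdr(labels: pd.DataFrame, truth: SimulationTruth,
                 fdr_target: float = 0.05) -> EvaluationResult:
    """Power at a fixed FDR and the precision-recall curve.

    ``labels`` is the classify_hits output in rank order (most
    significant first).  At each prefix the TP/FP-cluster counting of
    :func:`count_tp_fp` applies.
    """
    m = truth.m
    rows = []
    power = 0.0
    for k in range(1, len(labels) + 1):
        tp, fpc = count_tp_fp(labels.iloc[:k])
        denom = tp + fpc
        fdr = fpc / denom if denom else 0.0
        recall = tp / m if m else 0.0
        precision = tp / denom if denom else 1.0
        rows.append((k, tp, fpc, recall, precision, fdr))
        if fdr <= fdr_target:
            power = max(power, recall)
    curve = pd.DataFrame(rows, columns=["rank", "tp", "fp_clusters",
                                        "recall", "precision", "fdr"])
    tp_all, fp_all = count_tp_fp(labels) if len(labels) else (0, 0)
    return EvaluationResult(power, fdr_target, tp_all, fp_all, curve)


def evaluate_report(hits: pd.DataFrame, truth: SimulationTruth,
                    g: GenotypeDataset, fdr_target: float = 0.05,
                    r2_threshold: float = DEFAULT_R2_THRESHOLD
                    ) -> EvaluationResult:
    """classify_hits + power_at_fdr in one call."""
    labels = classify_hits(hits, truth, g, r2_threshold)
    return power_at_fdr(labels, truth, fdr_target)
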