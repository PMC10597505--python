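"""Clustering and genotyping metrics against simulator ground truth.

Four metrics: V-measure (harmonic mean of homogeneity and completeness of
the predicted partition against the true clone labels), genotyping
sensitivity (% of true 1s recovered), genotyping specificity (% of true 0s
recovered) and genotyping accuracy (% of all entries recovered).  Doublet
cells are excluded from every metric.  A majority-vote consensus
post-processor turns a ternary D matrix plus predicted labels into
per-cluster binary genotypes, imputing missing entries with fair coins.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import warnings

import numpy as np
from sklearn.metrics import homogeneity_completeness_v_measure

from .noise import MISSING

__all__ = [
    "Prediction",
    "EvaluationReport",
    "v_measure",
    "genotyping_sensitivity",
    "genotyping_specificity",
    "genotyping_accuracy",
    "estimated_cluster_count",
    "consensus_by_majority",
    "evaluate",
]


@dataclass
class Prediction:
    """Container for an external tool's output."""

    labels: np.ndarray
    genotypes: np.ndarray | None = None  # N' x M binary, optional


@dataclass
class EvaluationReport:
    v_measure: float
    sensitivity: float | None = None  # percent
    specificity: float | None = None  # percent
    accuracy: float | None = None  # percent
    n_clusters_estimated: int = 0
    n_cells_scored: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def v_measure(true_labels, pred_labels) -> float:
    """V-measure in [0, 1]; 1 iff the partitions agree up to renaming."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    if true_labels.size == 0:
        raise ValueError("empty input")
    if true_labels.shape != pred_labels.shape:
        raise ValueError("label vectors differ in length")
    _, _, v = homogeneity_completeness_v_measure(true_labels, pred_labels)
    return float(v)


def _binary_pair(G, inferred):
    g = np.asarray(G.values if hasattr(G, "values") else G)
    d = np.asarray(inferred.values if hasattr(inferred, "values") else inferred)
    if g.shape != d.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {d.shape}")
    return g, d


def genotyping_sensitivity(G, inferred) -> float:
    """Percent of ground-truth 1s reported as 1."""
    g, d = _binary_pair(G, inferred)
    n1 = int((g == 1).sum())
    if n1 == 0:
        raise ValueError("ground truth has no 1 entries; sensitivity undefined")
    return 100.0 * int(((g == 1) & (d == 1)).sum()) / n1


def genotyping_specificity(G, inferred) -> float:
    """Percent of ground-truth 0s reported as 0."""
    g, d = _binary_pair(G, inferred)
    n0 = int((g == 0).sum())
    if n0 == 0:
        raise ValueError("ground truth has no 0 entries; specificity undefined")
    return 100.0 * int(((g == 0) & (d == 0)).sum()) / n0


def genotyping_accuracy(G, inferred) -> float:
    """Percent of all entries reported correctly."""
    g, d = _binary_pair(G, inferred)
    return 100.0 * int((g == d).sum()) / g.size


def estimated_cluster_count(pred_labels) -> int:
    labels = np.asarray(pred_labels)
    if labels.size == 0:
        raise ValueError("empty input")
    return int(len(np.unique(labels)))


def consensus_by_majority(D, pred_labels, seed=None, clusters=None):
    """Majority-vote consensus genotype per predicted cluster.

    Missing entries are imputed independently per cell with a fair coin
    before the vote; a tied vote is broken by another fair coin.  Returns
    ``(consensus, inferred)`` where ``consensus`` maps cluster label to its
    binary genotype vector and ``inferred`` is the per-cell matrix in which
    every cell carries its cluster's consensus.
    """
    d = np.asarray(D.values if hasattr(D, "values") else D)
    labels = np.asarray(pred_labels)
    if labels.size != d.shape[0]:
        raise ValueError("labels length does not match D rows")
    rng = np.random.default_rng(seed)
    inferred = np.zeros(d.shape, dtype=np.int8)
    consensus: dict = {}
    cluster_ids = np.unique(labels) if clusters is None else clusters
    for lab in cluster_ids:
        rows = d[labels == lab]
        if rows.size == 0:
            warnings.warn(f"cluster {lab!r} is empty; skipped")
            continue
        n = rows.shape[0]
        miss = rows == MISSING
        ones = (rows == 1).sum(axis=0)
        ones = ones + rng.binomial(miss.sum(axis=0), 0.5)
        votes = np.where(2 * ones > n, 1, 0).astype(np.int8)
        ties = 2 * ones == n
        if ties.any():
            votes[ties] = rng.integers(0, 2, size=int(ties.sum()))
        consensus[lab] = votes
        inferred[labels == lab] = votes
    return consensus, inferred


def evaluate(
    true_labels,
    pred_labels,
    G=None,
    inferred_genotypes=None,
    doublet_flags=None,
) -> EvaluationReport:
    """Score a prediction against the truth, excluding doublet cells.

    ``G`` and ``inferred_genotypes`` are optional; genotyping metrics are
    reported only when both are given.
    """
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    keep = np.ones(true_labels.size, dtype=bool)
    if doublet_flags is not None:
        keep = ~np.asarray(doublet_flags, dtype=bool)
    t, p = true_labels[keep], pred_labels[keep]

    report = EvaluationReport(
        v_measure=v_measure(t, p),
        n_clusters_estimated=estimated_cluster_count(p),
        n_cells_scored=int(keep.sum()),
    )
    if G is not None and inferred_genotypes is not None:
        g = np.asarray(G.values if hasattr(G, "values") else G)[keep]
        d = np.asarray(
            inferred_genotypes.values if hasattr(inferred_genotypes, "values") else inferred_genotypes
        )[keep]
        report.sensitivity = genotyping_sensitivity(g, d)
        report.specificity = genotyping_specificity(g, d)
        report.accuracy = genotyping_accuracy(g, d)
    return report
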