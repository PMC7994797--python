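"""Metrics and statistics: AUROC/F1/sensitivity/specificity, worklist
sensitivity curves, bootstrap confidence intervals over per-seed scores,
paired permutation tests with Bonferroni correction, and median-of-seeds
ensembling.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "binary_metrics",
    "worklist_sensitivity",
    "bootstrap_ci",
    "paired_permutation_test",
    "bonferroni",
    "ensemble_median",
]


def binary_metrics(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> dict[str, float]:
    """AUROC (midrank tie handling) plus thresholded F1/sensitivity/
    specificity/PPV.

    Raises when labels contain a single class (AUROC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC undefined: labels contain a single class")
    auroc = float(roc_auc_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return {
        "auroc": auroc,
        "f1": f1,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "ppv": ppv,
    }


def worklist_sensitivity(
    scores: Sequence[float], labels: Sequence[int], fraction: float
) -> float:
    """Sensitivity when only the top `fraction` of the score-sorted worklist
    is read.

    Exams are ranked by descending score with ties broken stably by input
    order; the top ceil(fraction * N) exams are read and the captured share
    of positives returned.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positive exams in the worklist")
    n_read = int(np.ceil(fraction * len(scores)))
    order = np.argsort(-scores, kind="stable")
    captured = int(labels[order[:n_read]].sum())
    return captured / n_pos


def bootstrap_ci(
    per_seed_scores: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    rng: Optional[np.random.Generator] = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI of the mean of a small sample of scores
    (typically n = 5 seeds). Returns (mean, lo, hi)."""
    rng = rng or np.random.default_rng()
    scores = np.asarray(per_seed_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score sample")
    idx = rng.integers(0, scores.size, size=(n_boot, scores.size))
    means = scores[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(scores.mean()), float(lo), float(hi)


def paired_permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    sides: int = 1,
    n_iter: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Sign-flip permutation test on paired differences.

    One-sided tests H0: mean(a) <= mean(b). When 2^n <= n_iter the test is
    exact (full enumeration of sign patterns, p = #extreme / 2^n); otherwise
    sign flips are sampled and p = (1 + #extreme) / (1 + n_iter).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1D paired samples")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    diff = a - b
    observed = diff.mean()
    if sides == 2:
        observed = abs(observed)
    n = diff.size
    if 2**n <= n_iter:
        signs = np.array(
            [[1 if (mask >> i) & 1 else -1 for i in range(n)] for mask in range(2**n)]
        )
        stats = (signs * diff).mean(axis=1)
        if sides == 2:
            stats = np.abs(stats)
        return float(np.sum(stats >= observed) / len(stats))
    rng = rng or np.random.default_rng()
    signs = rng.choice([-1.0, 1.0], size=(n_iter, n))
    stats = (signs * diff).mean(axis=1)
    if sides == 2:
        stats = np.abs(stats)
    extreme = int(np.sum(stats >= observed))
    return float((1 + extreme) / (1 + n_iter))


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Bonferroni-corrected p-values (capped at 1)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


def ensemble_median(per_seed_predictions: Sequence[Sequence[float]]) -> np.ndarray:
    """Elementwise median across per-seed score vectors.

    With an even seed count the median is the mean of the two central
    values (numpy convention).
    """
    stacked = np.asarray(per_seed_predictions, dtype=float)
    if stacked.ndim != 2:
        raise ValueError("expected a list of equal-length score vectors")
    return np.median(stacked, axis=0)
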