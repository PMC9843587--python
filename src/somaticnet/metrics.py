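"""Per-sample evaluation: ROC-AUC, f1 with the median-of-optimal-thresholds
procedure, pre-/post-filter recall accounting and sample-level CV splits.

Two denominators matter here. The ROC curve (and its AUC) is computed on the
variants that survive population filtering. The f1-score instead charges the
pipeline for somatic variants lost to the filter: its recall denominator is
the number of ground-truth somatic variants *before* filtering. Samples with
fewer than 10 positive or 10 negative post-filter labels are excluded from
reporting; the operating threshold is the median of the per-sample optimal
thresholds of the remaining samples, and every sample's f1 is then
recomputed at that shared threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class SampleEvaluation:
    """Scores, labels and summary metrics for one sample (patient)."""

    sample_id: str
    scores: np.ndarray
    labels: np.ndarray  # 1 = somatic, 0 = non-somatic; post-filter
    n_somatic_prefilter: int
    auc: float = float("nan")
    roc_fpr: np.ndarray = field(default_factory=lambda: np.empty(0))
    roc_tpr: np.ndarray = field(default_factory=lambda: np.empty(0))
    optimal_threshold: float = float("nan")
    f1: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")
    threshold: float = float("nan")
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have the same shape")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, np.ndarray, np.ndarray]:
    """ROC-AUC with the full threshold-sweep curve.

    The AUC equals the probability that a randomly chosen positive scores
    above a randomly chosen negative (ties counted half). Raises on
    single-class input.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC undefined: only one class present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr)), fpr, tpr


def f1_at_threshold(
    scores: Sequence[float],
    labels_postfilter: Sequence[int],
    n_somatic_prefilter: int,
    t: float,
) -> tuple[float, float, float]:
    """(f1, precision, recall) at cutoff ``t`` (predicted somatic iff score > t).

    Recall divides true positives by the pre-filter somatic count, so somatic
    variants removed by population filtering count as misses. f1 is 0 when
    precision + recall is 0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels_postfilter, dtype=int)
    called = scores > t
    tp = int(np.sum(called & (labels == 1)))
    fp = int(np.sum(called & (labels == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / n_somatic_prefilter if n_somatic_prefilter else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return f1, precision, recall


def optimal_threshold(
    scores: Sequence[float],
    labels_postfilter: Sequence[int],
    n_somatic_prefilter: int,
) -> tuple[float, float]:
    """(t, f1) maximizing f1 over the observed score set; ties take the lowest t.

    The threshold grid is exactly the set of observed scores (plus 0, so the
    call-everything operating point is reachable): every achievable
    confusion matrix under the strict ``score > t`` rule corresponds to one
    of these cutoffs.
    """
    scores = np.asarray(scores, dtype=float)
    grid = np.unique(np.concatenate([[0.0], scores]))
    best_t, best_f1 = grid[0], -1.0
    for t in grid:
        f1, _, _ = f1_at_threshold(scores, labels_postfilter, n_somatic_prefilter, t)
        if f1 > best_f1 + 1e-15:
            best_t, best_f1 = t, f1
    return float(best_t), float(best_f1)


def evaluate_sample(
    sample_id: str,
    scores: Sequence[float],
    labels: Sequence[int],
    n_somatic_prefilter: int | None = None,
    min_labels: int = 10,
) -> SampleEvaluation:
    """Build a :class:`SampleEvaluation` with AUC and the per-sample optimal f1."""
    ev = SampleEvaluation(
        sample_id=sample_id,
        scores=np.asarray(scores, float),
        labels=np.asarray(labels, int),
        n_somatic_prefilter=int(n_somatic_prefilter if n_somatic_prefilter is not None else np.sum(np.asarray(labels) == 1)),
    )
    n_pos = int(np.sum(ev.labels == 1))
    n_neg = int(np.sum(ev.labels == 0))
    if n_pos < min_labels or n_neg < min_labels:
        ev.excluded = True
        ev.exclusion_reason = f"{n_pos} positive / {n_neg} negative labels (< {min_labels})"
        return ev
    ev.auc, ev.roc_fpr, ev.roc_tpr = roc_auc(ev.scores, ev.labels)
    ev.optimal_threshold, _ = optimal_threshold(ev.scores, ev.labels, ev.n_somatic_prefilter)
    return ev


def select_median_threshold(per_sample_evals: Sequence[SampleEvaluation]) -> float:
    """Median of per-sample optimal thresholds over non-excluded samples.

    Each evaluation is updated in place with f1/precision/recall recomputed
    at the shared median threshold.
    """
    active = [ev for ev in per_sample_evals if not ev.excluded]
    if not active:
        raise ValueError("all samples excluded; cannot select a threshold")
    t_median = float(np.median([ev.optimal_threshold for ev in active]))
    for ev in active:
        ev.threshold = t_median
        ev.f1, ev.precision, ev.recall = f1_at_threshold(
            ev.scores, ev.labels, ev.n_somatic_prefilter, t_median
        )
    return t_median


def evaluate_samples(
    per_sample: dict[str, tuple[Sequence[float], Sequence[int]]],
    prefilter_somatic: dict[str, int] | None = None,
    min_labels: int = 10,
) -> tuple[list[SampleEvaluation], float]:
    """Evaluate a cohort: per-sample AUC/optimal thresholds, then the shared
    median threshold and per-sample f1 at it.

    ``per_sample`` maps sample id to (scores, post-filter labels);
    ``prefilter_somatic`` maps sample id to the pre-filter somatic count
    (defaults to the post-filter positive count).
    """
    evals = []
    for sid, (scores, labels) in per_sample.items():
        npre = None if prefilter_somatic is None else prefilter_somatic.get(sid)
        evals.append(evaluate_sample(sid, scores, labels, npre, min_labels=min_labels))
    t_median = select_median_threshold(evals)
    return evals, t_median


def subset_view(
    scores: Sequence[float],
    truth_labels: Sequence[str],
    view: str = "somatic_vs_all",
) -> tuple[np.ndarray, np.ndarray]:
    """Scores/binary labels for one classification view.

    Views: ``somatic_vs_all`` keeps everything, ``somatic_vs_germline`` drops
    artifacts, ``somatic_vs_artifact`` drops germline variants. Separate
    cutoffs are then chosen per view.
    """
    scores = np.asarray(scores, float)
    truth = np.asarray(truth_labels, dtype=object)
    if view == "somatic_vs_all":
        keep = np.ones(len(truth), bool)
    elif view == "somatic_vs_germline":
        keep = truth != "artifact"
    elif view == "somatic_vs_artifact":
        keep = truth != "germline"
    else:
        raise ValueError(f"unknown view {view!r}")
    return scores[keep], (truth[keep] == "somatic").astype(int)


def make_cv_splits(sample_ids: Sequence[str], k: int, seed: int) -> list[tuple[list[str], list[str]]]:
    """k-fold cross-validation partitions at the sample (patient) level.

    Returns ``[(train_ids, test_ids), ...]``; test folds are disjoint, cover
    all samples and differ in size by at most one. The shuffle is seeded.
    """
    ids = list(sample_ids)
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of samples ({len(ids)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, j in enumerate(order):
        folds[i % k].append(ids[j])
    splits = []
    for f in range(k):
        test = sorted(folds[f])
        train = sorted(x for g in range(k) if g != f for x in folds[g])
        splits.append((train, test))
    return splits


def summarize(evals: Sequence[SampleEvaluation]) -> dict[str, float]:
    """Mean and SD of AUC and f1 over non-excluded samples."""
    active = [ev for ev in evals if not ev.excluded]
    aucs = np.array([ev.auc for ev in active])
    f1s = np.array([ev.f1 for ev in active if not np.isnan(ev.f1)])
    return {
        "n_samples": len(active),
        "n_excluded": len(evals) - len(active),
        "auc_mean": float(np.mean(aucs)) if aucs.size else float("nan"),
        "auc_sd": float(np.std(aucs)) if aucs.size else float("nan"),
        "f1_mean": float(np.mean(f1s)) if f1s.size else float("nan"),
        "f1_sd": float(np.std(f1s)) if f1s.size else float("nan"),
    }
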