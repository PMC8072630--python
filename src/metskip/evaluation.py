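"""Evaluation and discovery: confusion arithmetic, ROC, latent clustering
with a stability score, and the repeat (LINE-1) screen of half-mapped mates.

Percentage conventions follow the benchmark report: sensitivity is
TP / P and "overall" specificity is (N - FP) / N over the whole cohort —
the arithmetic consistent with every printed value — and percentages are
*truncated* (not rounded) at the printed number of decimals.  The
classical TN / (TN + FP) specificity is provided alongside.
"""

from __future__ import annotations

import math
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.metrics import silhouette_score

from .errors import DataError
from .featurization import _window_codes, _encode
from .gene_model import reverse_complement
from .read_io import AlignedRead


# ---------------------------------------------------------------------------
# confusion-summary arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionSummary:
    """Cohort-level counts: N samples, P true events, and the model's calls."""

    total: int
    positives: int
    predicted_positive: int
    true_positive: int

    def __post_init__(self) -> None:
        if not (0 <= self.positives <= self.total):
            raise DataError("positives must lie in [0, total]")
        if self.true_positive > min(self.positives, self.predicted_positive):
            raise DataError("true positives exceed positives or predicted positives")
        if self.predicted_positive > self.total:
            raise DataError("predicted positives exceed total")

    @property
    def false_positive(self) -> int:
        return self.predicted_positive - self.true_positive

    @classmethod
    def from_calls(cls, labels, calls, positive="delta14") -> "ConfusionSummary":
        lab = np.asarray(labels) == positive
        cal = np.asarray(calls) == positive
        return cls(
            total=lab.size,
            positives=int(lab.sum()),
            predicted_positive=int(cal.sum()),
            true_positive=int((lab & cal).sum()),
        )


def truncate_pct(value: float, decimals: int = 1) -> float:
    """Floor a percentage at the requested number of decimals."""
    scale = 10**decimals
    return math.floor(value * scale) / scale


def prevalence_pct(cs: ConfusionSummary, decimals: int = 2) -> float:
    """Fraction of true events in the cohort, truncated percentage."""
    if cs.total == 0:
        raise DataError("empty cohort")
    return truncate_pct(100.0 * cs.positives / cs.total, decimals)


def sensitivity_pct(cs: ConfusionSummary, decimals: int = 1) -> float:
    """100 * TP / P, truncated."""
    if cs.positives == 0:
        raise DataError("sensitivity undefined: no true events in the cohort")
    return truncate_pct(100.0 * cs.true_positive / cs.positives, decimals)


def specificity_overall_pct(cs: ConfusionSummary, decimals: int = 1) -> float:
    """100 * (N - FP) / N, truncated — the benchmark-report convention."""
    if cs.total == 0:
        raise DataError("empty cohort")
    return truncate_pct(100.0 * (cs.total - cs.false_positive) / cs.total, decimals)


def specificity_classical_pct(cs: ConfusionSummary, decimals: int = 1) -> float:
    """100 * TN / (TN + FP), truncated — the textbook definition."""
    negatives = cs.total - cs.positives
    if negatives == 0:
        raise DataError("specificity undefined: no negatives in the cohort")
    tn = negatives - cs.false_positive
    if tn < 0:
        raise DataError("false positives exceed negatives")
    return truncate_pct(100.0 * tn / negatives, decimals)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc(scores, labels, positive="delta14") -> ROCResult:
    """Standard threshold-sweep ROC with trapezoidal AUC."""
    y = np.asarray(labels)
    if y.dtype.kind not in "ifb":
        y = (y == positive).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise DataError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y, s)
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=float(_sk_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# latent-space normalization, clustering, stability
# ---------------------------------------------------------------------------

def normalize_latent_input(features: np.ndarray) -> np.ndarray:
    """Normalization chain applied before autoencoder training: per-sample
    frequency, scaled to counts-per-10k, log1p, then per-feature z-score
    (zero-variance features map to 0).  All-zero samples stay zero."""
    X = np.asarray(features, dtype=np.float64)
    if np.any(X < 0):
        raise DataError("latent-input normalization expects non-negative features")
    sums = X.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    X = np.log1p(X / sums * 1e4)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    out = np.zeros_like(X)
    # features constant up to floating-point noise count as zero-variance
    nz = sd > 1e-9 * np.maximum(1.0, np.abs(mu))
    out[:, nz] = (X[:, nz] - mu[nz]) / sd[nz]
    return out


@dataclass(frozen=True)
class ClusterResult:
    assignments: np.ndarray  # cluster id per sample
    k: int
    seed: int


def cluster_latent(
    latent: np.ndarray,
    k_candidates: tuple[int, ...] = (2, 3, 4, 5, 6),
    n_runs: int = 10,
    seed: int = 0,
) -> list[ClusterResult]:
    """Repeated k-means over the latent space, best k per run by silhouette.

    Each run uses its own sub-seed and a single random initialization, so
    run-to-run agreement reflects how well-determined the clustering is —
    the quantity :func:`cluster_stability` scores.
    """
    X = np.asarray(latent, dtype=np.float64)
    if n_runs < 2:
        raise DataError("n_runs must be >= 2 for a stability assessment")
    if X.shape[0] < max(k_candidates) + 1:
        raise DataError("fewer samples than clusters requested")
    results = []
    for r in range(n_runs):
        sub = seed + r
        best = None
        for k in k_candidates:
            km = KMeans(n_clusters=k, n_init=1, random_state=sub).fit(X)
            sil = silhouette_score(X, km.labels_) if len(set(km.labels_)) > 1 else -1.0
            if best is None or sil > best[0]:
                best = (sil, k, km.labels_)
        results.append(ClusterResult(assignments=best[2].copy(), k=best[1], seed=sub))
    return results


@dataclass(frozen=True)
class StabilityScore:
    per_cluster: dict
    overall: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.overall <= 1.0:
            raise DataError("overall stability out of [0, 1]")


def _best_match_jaccard(a: np.ndarray, b: np.ndarray) -> dict[int, float]:
    """For each cluster of `a`, its best Jaccard overlap with any cluster of `b`."""
    out = {}
    for ca in np.unique(a):
        sa = set(np.nonzero(a == ca)[0].tolist())
        best = 0.0
        for cb in np.unique(b):
            sb = set(np.nonzero(b == cb)[0].tolist())
            j = len(sa & sb) / len(sa | sb)
            best = max(best, j)
        out[int(ca)] = best
    return out


def cluster_stability(
    results: list[ClusterResult],
    n_pairs: int = 1000,
    seed: int = 0,
) -> StabilityScore:
    """Agreement of cluster memberships across randomly paired runs.

    For each sampled pair of runs, every cluster is matched to its best
    Jaccard counterpart in the other run (symmetrized); the per-cluster
    score (keyed by the first run's cluster ids) averages each cluster's
    best match against every other run, and the overall score averages the
    pair scores.  Identical partitions in all runs score exactly 1.
    """
    if len(results) < 2:
        raise DataError("need at least two clustering runs")
    n = results[0].assignments.size
    if any(r.assignments.size != n for r in results):
        raise DataError("clustering runs cover different sample sets")
    all_pairs = [(i, j) for i in range(len(results)) for j in range(i + 1, len(results))]
    rng = np.random.default_rng(seed)
    if len(all_pairs) > n_pairs:
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        pairs = [all_pairs[i] for i in idx]
    else:
        pairs = all_pairs
    pair_scores = []
    for i, j in pairs:
        ab = _best_match_jaccard(results[i].assignments, results[j].assignments)
        ba = _best_match_jaccard(results[j].assignments, results[i].assignments)
        pair_scores.append(
            0.5 * (float(np.mean(list(ab.values()))) + float(np.mean(list(ba.values()))))
        )
    ref = results[0]
    per_cluster: dict[int, list[float]] = {int(c): [] for c in np.unique(ref.assignments)}
    for other in results[1:]:
        for c, j in _best_match_jaccard(ref.assignments, other.assignments).items():
            per_cluster[c].append(j)
    per_cluster_mean = {c: float(np.mean(v)) for c, v in per_cluster.items()}
    return StabilityScore(
        per_cluster=per_cluster_mean,
        overall=float(np.mean(pair_scores)),
        n_pairs=len(pairs),
    )


# ---------------------------------------------------------------------------
# repeat screen of half-mapped mate pairs
# ---------------------------------------------------------------------------

RepeatHit = namedtuple("RepeatHit", ["read_name", "kmer", "chrom", "fusion_point"])


def repeat_screen(
    pairs: list[tuple[AlignedRead, AlignedRead]],
    repeat_sequence: str,
    k: int = 31,
) -> list[RepeatHit]:
    """Exact k-mer seed screen of non-locus mates against a repeat sequence.

    A mate "matches" when it shares at least one exact k-mer with the
    repeat in either orientation.  The putative fusion point is the locus
    coordinate (1-based) of the locus-anchored mate's alignment start.
    """
    if k < 2:
        raise DataError("k must be >= 2")
    if len(repeat_sequence) < k:
        raise DataError("repeat sequence shorter than k")
    codes, valid = _window_codes(_encode(repeat_sequence), k)
    repeat_kmers = np.unique(codes[valid])
    hits: list[RepeatHit] = []
    for locus_read, mate in pairs:
        if len(mate.sequence) < k or locus_read.span is None:
            continue
        found = None
        for seq in (mate.sequence, reverse_complement(mate.sequence)):
            c, v = _window_codes(_encode(seq), k)
            pos = np.searchsorted(repeat_kmers, c)
            pos_c = np.minimum(pos, len(repeat_kmers) - 1)
            shared = np.nonzero(v & (pos < len(repeat_kmers)) & (repeat_kmers[pos_c] == c))[0]
            if shared.size:
                found = seq[shared[0] : shared[0] + k]
                break
        if found is not None:
            span = locus_read.span
            hits.append(RepeatHit(locus_read.name, found, span.chrom, span.start + 1))
    return hits
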