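"""Detection-quality evaluation against a manual reference.

Given a software-detected cell set and a manually annotated reference set
for the same field, points are paired by mutually-greedy nearest-neighbor
matching within a radius (default 10 um, about one lymphocyte diameter).
Matched pairs are true positives; unmatched detections are false positives;
unmatched reference cells are false negatives.  Recall R = TP/(TP+FN) and
precision P = TP/(TP+FP) are reported with binomial standard errors
sqrt(p(1-p)/n), and agreement between per-sample detected and reference
counts is summarized by Spearman's rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import spearmanr

from .core_io import PointPattern, UndefinedMetricError

DEFAULT_MATCH_RADIUS = 10.0  # um


@dataclass
class MatchResult:
    """Outcome of matching a detected against a reference point set."""

    TP: int
    FP: int
    FN: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP != len(self.pairs):
            raise ValueError("TP must equal the number of matched pairs")


@dataclass
class EvalSummary:
    """Pooled recall/precision with standard errors and count agreement."""

    TP: int
    FP: int
    FN: int
    R: float
    P: float
    se_R: float
    se_P: float
    spearman_rho: float  # NaN when per-sample counts are degenerate


def match_points(
    detected: PointPattern | np.ndarray,
    reference: PointPattern | np.ndarray,
    radius: float = DEFAULT_MATCH_RADIUS,
) -> MatchResult:
    """Mutually-greedy nearest-neighbor matching within ``radius``.

    Repeatedly pairs the globally closest unmatched (detected, reference)
    pair at distance <= radius.  Each point participates in at most one
    pair.  Deterministic; ties broken by (distance, detected index,
    reference index).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    det = detected.points if isinstance(detected, PointPattern) else np.asarray(detected, float).reshape(-1, 2)
    ref = reference.points if isinstance(reference, PointPattern) else np.asarray(reference, float).reshape(-1, 2)
    if len(det) == 0 or len(ref) == 0:
        return MatchResult(TP=0, FP=len(det), FN=len(ref), pairs=[])

    tree = cKDTree(ref)
    # candidate edges within the radius, sorted once: greedy extraction of
    # the globally closest unmatched pair is then a single linear sweep
    neighbor_lists = tree.query_ball_point(det, r=radius)
    edges: list[tuple[float, int, int]] = []
    for i, js in enumerate(neighbor_lists):
        for j in js:
            d = float(np.hypot(*(det[i] - ref[j])))
            edges.append((d, i, j))
    edges.sort()

    det_used = np.zeros(len(det), dtype=bool)
    ref_used = np.zeros(len(ref), dtype=bool)
    pairs: list[tuple[int, int, float]] = []
    for d, i, j in edges:
        if not det_used[i] and not ref_used[j]:
            det_used[i] = ref_used[j] = True
            pairs.append((i, j, d))
    tp = len(pairs)
    return MatchResult(TP=tp, FP=len(det) - tp, FN=len(ref) - tp, pairs=pairs)


def recall(TP: int, FN: int) -> float:
    """Sensitivity TP/(TP+FN)."""
    if TP + FN <= 0:
        raise UndefinedMetricError("recall undefined: no reference cells (TP+FN=0)")
    return TP / (TP + FN)


def precision(TP: int, FP: int) -> float:
    """Positive predictive value TP/(TP+FP)."""
    if TP + FP <= 0:
        raise UndefinedMetricError("precision undefined: no detections (TP+FP=0)")
    return TP / (TP + FP)


def se_proportion(p: float, n: int) -> float:
    """Binomial standard error sqrt(p(1-p)/n)."""
    if n <= 0:
        raise UndefinedMetricError("standard error undefined for n=0")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return float(np.sqrt(p * (1.0 - p) / n))


def summarize_counts(TP: int, FP: int, FN: int, spearman_rho: float = float("nan")) -> EvalSummary:
    """Recall/precision summary from pooled counts."""
    R = recall(TP, FN)
    P = precision(TP, FP)
    return EvalSummary(
        TP=TP, FP=FP, FN=FN, R=R, P=P,
        se_R=se_proportion(R, TP + FN),
        se_P=se_proportion(P, TP + FP),
        spearman_rho=spearman_rho,
    )


def evaluate_samples(
    sample_pairs: Sequence[tuple[PointPattern | np.ndarray, PointPattern | np.ndarray]],
    radius: float = DEFAULT_MATCH_RADIUS,
) -> EvalSummary:
    """Pool TP/FP/FN over sample regions and summarize.

    Spearman's rho is computed over the per-sample (detected count,
    reference count) pairs, i.e. (TP+FP) vs (TP+FN), with midrank ties; it
    is NaN when either count vector is constant.
    """
    if len(sample_pairs) == 0:
        raise UndefinedMetricError("at least one sample region is required")
    TP = FP = FN = 0
    det_counts, ref_counts = [], []
    for det, ref in sample_pairs:
        m = match_points(det, ref, radius=radius)
        TP += m.TP
        FP += m.FP
        FN += m.FN
        det_counts.append(m.TP + m.FP)
        ref_counts.append(m.TP + m.FN)
    if TP + FN == 0 and TP + FP == 0:
        raise UndefinedMetricError("all sample regions are empty")
    if len(det_counts) >= 2 and np.std(det_counts) > 0 and np.std(ref_counts) > 0:
        rho = float(spearmanr(det_counts, ref_counts).statistic)
    else:
        rho = float("nan")
    return summarize_counts(TP, FP, FN, spearman_rho=rho)
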