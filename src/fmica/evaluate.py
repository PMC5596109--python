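"""Evaluation utilities: spatial correlation, template matching, recovery
reports, group contrasts and the Amari separation index."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .core import FeatureMapSet

__all__ = [
    "MatchResult",
    "RecoveryReport",
    "TTestResult",
    "spatial_correlation",
    "match_components",
    "recovery_report",
    "contrast_ttest",
    "amari_index",
]


def _as_maps(x) -> np.ndarray:
    return x.maps if isinstance(x, FeatureMapSet) else np.atleast_2d(np.asarray(x, float))


@dataclass
class MatchResult:
    """Injective assignment of templates to components, by |correlation|."""

    assignment: dict                # template index -> component index
    correlations: dict              # template index -> signed Pearson r
    unmatched_templates: list = field(default_factory=list)
    unmatched_components: list = field(default_factory=list)


@dataclass
class RecoveryReport:
    per_source_r: np.ndarray
    mean: float
    sd: float
    match: MatchResult


@dataclass
class TTestResult:
    t: float
    p: float
    mean_a: float
    mean_b: float


def spatial_correlation(map_a, map_b) -> float:
    """Pearson correlation between two spatial maps over in-mask voxels."""
    a = np.asarray(map_a, float).ravel()
    b = np.asarray(map_b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("maps differ in length")
    if min(a.std(), b.std()) <= 1e-12 * max(1.0, float(np.abs(a).max()),
                                             float(np.abs(b).max())):
        raise ValueError("correlation undefined for a constant map")
    return float(np.corrcoef(a, b)[0, 1])


def _correlation_matrix(T: np.ndarray, C: np.ndarray) -> np.ndarray:
    Ts = (T - T.mean(axis=1)[:, None]) / T.std(axis=1)[:, None]
    Cs = (C - C.mean(axis=1)[:, None]) / C.std(axis=1)[:, None]
    return Ts @ Cs.T / T.shape[1]


def match_components(estimated, templates, method: str = "greedy") -> MatchResult:
    """Injectively match templates to estimated components by max |r|.

    ``method='greedy'`` picks pairs in descending |r| without replacement;
    ``method='optimal'`` solves the assignment problem (Hungarian) on
    -|r|. Output is invariant to component order and sign flips.
    """
    C = _as_maps(estimated)
    T = _as_maps(templates)
    if C.shape[1] != T.shape[1]:
        raise ValueError("estimated and template maps differ in voxel dimension")
    R = _correlation_matrix(T, C)
    n_t, n_c = R.shape
    assignment, correlations = {}, {}
    if method == "greedy":
        A = np.abs(R).copy()
        for _ in range(min(n_t, n_c)):
            i, j = np.unravel_index(np.argmax(A), A.shape)
            if not np.isfinite(A[i, j]):
                break
            assignment[int(i)] = int(j)
            correlations[int(i)] = float(R[i, j])
            A[i, :] = -np.inf
            A[:, j] = -np.inf
    elif method == "optimal":
        k = min(n_t, n_c)
        rows, cols = linear_sum_assignment(-np.abs(R))
        for i, j in zip(rows[:], cols[:]):
            assignment[int(i)] = int(j)
            correlations[int(i)] = float(R[i, j])
        if len(assignment) > k:  # pragma: no cover - lsa returns min(n_t, n_c) pairs
            raise RuntimeError
    else:
        raise ValueError(f"unknown method {method!r}")
    unmatched_t = sorted(set(range(n_t)) - set(assignment))
    unmatched_c = sorted(set(range(n_c)) - set(assignment.values()))
    return MatchResult(assignment, correlations, unmatched_t, unmatched_c)


def recovery_report(estimated, truth, method: str = "greedy") -> RecoveryReport:
    """Match estimated maps to ground truth and summarize per-source r."""
    match = match_components(estimated, truth, method=method)
    n_t = _as_maps(truth).shape[0]
    if match.unmatched_templates:
        raise ValueError(
            f"truth sources {match.unmatched_templates} unmatched "
            "(fewer estimated components than sources)"
        )
    r = np.array([match.correlations[i] for i in range(n_t)])
    return RecoveryReport(per_source_r=r, mean=float(r.mean()),
                          sd=float(r.std(ddof=1)) if r.size > 1 else 0.0,
                          match=match)


def contrast_ttest(group_a, group_b, equal_var: bool = False) -> TTestResult:
    """Two-sample t-test (Welch by default), two-sided."""
    a = np.asarray(list(group_a), float)
    b = np.asarray(list(group_b), float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups are degenerate (zero variance)")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(t), float(p), float(a.mean()), float(b.mean()))


def amari_index(P: np.ndarray) -> float:
    """Normalized Amari index of a gain matrix P = W_est @ A_true.

    0 for a perfect separation (P a scaled permutation), growing toward 1
    as rows/columns mix; invariant to permutation and scaling.
    """
    P = np.abs(np.asarray(P, float))
    k = P.shape[0]
    if P.shape[0] != P.shape[1]:
        raise ValueError("P must be square")
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * k * (k - 1)))
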