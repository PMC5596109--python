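"""Unconstrained ICA machinery: whitening, fixed-point ICA, order selection.

All matrices are channels-in-rows: ``data`` has shape (d, N) where each of
the d rows is one observed mixture (a time point of an fMRI run, or one
spatial feature map) sampled over N voxels.  The linear model is X = A S
with unmixing Y = W X; estimated sources Y are decorrelated with unit
(population) variance.

Three model-order rules are provided, matching the hierarchy's needs:

* :func:`estimate_order_laplace` -- Minka's Laplace-approximation evidence
  on the covariance eigenspectrum, used per subject at the first level;
* :func:`mean_order` -- rounded mean of the per-subject orders, used at the
  intragroup level;
* :func:`icasso_select` -- stability-based selection over a candidate
  range by repeated randomized ICA runs clustered by component similarity,
  used at the intergroup level when datasets are heterogeneous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln

__all__ = [
    "Whitening",
    "UnmixingModel",
    "OrderEstimate",
    "center_whiten",
    "fastica",
    "estimate_order_laplace",
    "mean_order",
    "icasso_select",
]

_EPS = 1e-12


@dataclass
class Whitening:
    """PCA whitening of a (d, N) channels x samples matrix.

    ``whitening @ (X - mean)`` has zero-mean rows with identity covariance;
    ``dewhitening`` maps whitened coordinates back into the retained
    subspace of the original space.
    """

    mean: np.ndarray           # (d,)
    whitening: np.ndarray      # (k, d)
    dewhitening: np.ndarray    # (d, k)
    requested_order: int
    order: int                 # effective order after rank reduction

    def whiten(self, data: np.ndarray) -> np.ndarray:
        return self.whitening @ (np.asarray(data, float) - self.mean[:, None])

    def dewhiten(self, z: np.ndarray) -> np.ndarray:
        return self.dewhitening @ z + self.mean[:, None]


@dataclass
class UnmixingModel:
    """One ICA decomposition X = A S, Y = W X (components in rows of Y)."""

    whitening: Whitening
    unmixing_whitened: np.ndarray   # (k, k) rotation in whitened space
    unmixing: np.ndarray            # (k, d) composite: Y = unmixing @ (X - mean)
    mixing: np.ndarray              # (d, k) pseudo-inverse sense
    sources: np.ndarray             # (k, N)
    n_iterations: int
    converged: bool
    seed: int

    @property
    def order(self) -> int:
        return self.sources.shape[0]


@dataclass
class OrderEstimate:
    """Result of a model-order selection rule."""

    method: str
    candidates: list
    scores: np.ndarray
    chosen: int
    detail: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.chosen not in self.candidates:
            raise ValueError("chosen order is not among the candidates")
        if not np.all(np.isfinite(np.asarray(self.scores, float))):
            raise ValueError("order-selection scores must be finite")


def center_whiten(data: np.ndarray, order: int) -> tuple[np.ndarray, Whitening]:
    """Center rows and PCA-whiten down to ``order`` dimensions.

    Returns the whitened (order, N) matrix and the transforms.  If the data
    have rank below the requested order, the effective order is reduced
    with a warning.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2D (channels x samples)")
    if not np.all(np.isfinite(X)):
        raise ValueError("data contains non-finite values")
    d, N = X.shape
    if order < 1 or order > min(d, N):
        raise ValueError(f"order must be in [1, {min(d, N)}], got {order}")
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    cov = (Xc @ Xc.T) / N
    evals, evecs = np.linalg.eigh(cov)      # ascending
    tol = evals[-1] * d * np.finfo(float).eps
    rank = int(np.sum(evals > max(tol, 0.0)))
    eff = order
    if rank < order:
        warnings.warn(
            f"data rank {rank} below requested order {order}; reducing",
            RuntimeWarning,
        )
        eff = max(rank, 1)
    lam = evals[-eff:][::-1]
    U = evecs[:, -eff:][:, ::-1]
    whitening = (U / np.sqrt(lam)).T
    dewhitening = U * np.sqrt(lam)
    wt = Whitening(mean, whitening, dewhitening, order, eff)
    return whitening @ Xc, wt


def _g_tanh(y):
    gy = np.tanh(y)
    return gy, 1.0 - gy ** 2


def _g_pow3(y):
    return y ** 3, 3.0 * y ** 2


_NONLINEARITIES = {"tanh": _g_tanh, "pow3": _g_pow3}


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    # W <- (W W^T)^{-1/2} W
    s, u = np.linalg.eigh(W @ W.T)
    s = np.clip(s, _EPS, None)
    return (u / np.sqrt(s)) @ u.T @ W


def fastica(
    data: np.ndarray,
    order: int,
    seed: int = 0,
    nonlinearity: str = "tanh",
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> UnmixingModel:
    """Fixed-point ICA with symmetric decorrelation (negentropy contrast).

    Parameters
    ----------
    data : ndarray, shape (d, N)
        Observed mixtures, channels in rows.
    order : int
        Number of components (PCA reduction happens first).
    seed : int
        Seed for the random orthogonal initialization.
    nonlinearity : {'tanh', 'pow3'}
        Contrast derivative g; 'tanh' is G(u) = log cosh u.
    max_iter, tol
        Stop when max_j |1 - |<w_j_new, w_j_old>|| < tol, or at max_iter
        (the best iterate is returned with ``converged=False``).

    Components are oriented to have positive skewness and sorted by
    descending variance explained in the original space.
    """
    if nonlinearity not in _NONLINEARITIES:
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    g = _NONLINEARITIES[nonlinearity]
    Z, wt = center_whiten(data, order)
    k, N = Z.shape
    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((k, k)))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Y = W @ Z
        gy, gpy = g(Y)
        W_new = (gy @ Z.T) / N - gpy.mean(axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        delta = np.max(np.abs(1.0 - np.abs(np.einsum("ij,ij->i", W_new, W))))
        W = W_new
        if delta < tol:
            converged = True
            break
    Y = W @ Z
    # sign convention: positive skewness, fallback largest-|value| positive
    skew = np.mean(Y ** 3, axis=1)
    flip = np.where(
        np.abs(skew) > 1e-8,
        np.sign(skew),
        np.sign(Y[np.arange(k), np.argmax(np.abs(Y), axis=1)]),
    )
    flip[flip == 0] = 1.0
    W = W * flip[:, None]
    composite = W @ wt.whitening
    A = np.linalg.pinv(composite)
    # order by variance explained in the original space: ||a_j||^2 per unit-var source
    idx = np.argsort(-np.sum(A ** 2, axis=0), kind="stable")
    W = W[idx]
    composite = composite[idx]
    A = A[:, idx]
    Y = composite @ (np.asarray(data, float) - wt.mean[:, None])
    return UnmixingModel(
        whitening=wt,
        unmixing_whitened=W,
        unmixing=composite,
        mixing=A,
        sources=Y,
        n_iterations=it,
        converged=converged,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# model order selection
# ---------------------------------------------------------------------------

def _laplace_log_evidence(spectrum: np.ndarray, k: int, n: int) -> float:
    """Minka's Laplace-approximation log evidence for retaining k components.

    ``spectrum`` holds the descending eigenvalues of the sample covariance
    of p variables estimated from n samples; 1 <= k < p.
    """
    p = spectrum.size
    if not 1 <= k < p:
        raise ValueError("k must satisfy 1 <= k < p")
    if spectrum[k - 1] < _EPS:
        return -np.inf
    v = max(float(np.sum(spectrum[k:])) / (p - k), _EPS)
    i = np.arange(1, k + 1)
    # uniform prior over the k-frame of eigenvectors (Stiefel manifold volume)
    log_pu = -k * np.log(2.0) + float(
        np.sum(gammaln((p - i + 1) / 2.0) - ((p - i + 1) / 2.0) * np.log(np.pi))
    )
    log_pl = -0.5 * n * float(np.sum(np.log(spectrum[:k])))
    log_pv = -0.5 * n * (p - k) * np.log(v)
    m = p * k - k * (k + 1) / 2.0
    log_pp = 0.5 * (m + k) * np.log(2.0 * np.pi)
    # Hessian determinant over eigenvalue separations
    spec_hat = spectrum.copy()
    spec_hat[k:] = v
    log_det_az = 0.0
    for a in range(k):
        diff = spectrum[a] - spectrum[a + 1 :]
        inv_diff = 1.0 / spec_hat[a + 1 :] - 1.0 / spec_hat[a]
        term = diff * inv_diff * n
        if np.any(term <= 0):
            return -np.inf
        log_det_az += float(np.sum(np.log(term)))
    return log_pu + log_pl + log_pv + log_pp - 0.5 * log_det_az - 0.5 * k * np.log(n)


def estimate_order_laplace(data: np.ndarray, max_order: int | None = None) -> OrderEstimate:
    """Choose the ICA model order by Minka's Laplace-approximation evidence.

    The eigenspectrum is taken over the smaller matrix dimension (for fMRI,
    time points), with the larger one (voxels) acting as the sample count.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2D")
    if X.shape[0] > X.shape[1]:
        X = X.T
    d, n = X.shape
    if n <= d:
        raise ValueError("need more samples than variables")
    Xc = X - X.mean(axis=1)[:, None]
    spectrum = np.linalg.eigvalsh((Xc @ Xc.T) / n)[::-1]
    spectrum = np.clip(spectrum, 0.0, None)
    hi = d - 1 if max_order is None else min(max_order, d - 1)
    candidates = list(range(1, hi + 1))
    scores = np.array([_laplace_log_evidence(spectrum, k, n) for k in candidates])
    finite = np.isfinite(scores)
    if not finite.any():
        raise ValueError("evidence non-finite for every candidate order")
    candidates = [c for c, f in zip(candidates, finite) if f]
    scores = scores[finite]
    chosen = candidates[int(np.argmax(scores))]
    return OrderEstimate("laplace", candidates, scores, chosen)


def mean_order(subject_orders) -> int:
    """Rounded (half-up) arithmetic mean of per-subject orders."""
    orders = list(subject_orders)
    if not orders:
        raise ValueError("subject_orders is empty")
    return int(np.floor(np.mean(orders) + 0.5))


def _stability_indices(pooled: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-cluster Iq = mean within-cluster |r| - mean between-cluster |r|."""
    sim = np.abs(np.corrcoef(pooled))
    iqs = []
    for lab in np.unique(labels):
        inside = labels == lab
        block = sim[np.ix_(inside, inside)]
        n_in = int(inside.sum())
        if n_in > 1:
            within = (block.sum() - n_in) / (n_in * (n_in - 1))
        else:
            within = 1.0
        outside = ~inside
        between = sim[np.ix_(inside, outside)].mean() if outside.any() else 0.0
        iqs.append(within - between)
    return np.asarray(iqs)


def icasso_select(
    data: np.ndarray,
    order_min: int,
    order_max: int,
    n_runs: int = 20,
    seed: int = 0,
    nonlinearity: str = "tanh",
    max_iter: int = 1000,
    tol: float = 1e-6,
    run_seeds=None,
) -> OrderEstimate:
    """Stability-based order selection over [order_min, order_max].

    For each candidate order, ``n_runs`` randomized fixed-point ICA runs are
    pooled and clustered by 1 - |correlation| dissimilarity (average
    linkage); the cluster stability index Iq summarizes compactness vs.
    isolation.  The chosen order maximizes the mean Iq, with smaller STD
    then smaller IQR of Iq as tie-breakers.

    ``run_seeds`` optionally fixes the per-run seeds (length ``n_runs``);
    by default they are derived independently per (seed, order, run).
    """
    if order_min > order_max:
        raise ValueError("order_min must be <= order_max")
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    candidates = list(range(order_min, order_max + 1))
    rows = []
    for q in candidates:
        pooled = []
        for run in range(n_runs):
            if run_seeds is not None:
                rs = int(run_seeds[run])
            else:
                rs = int(
                    np.random.SeedSequence([seed, q, run]).generate_state(1)[0]
                    % (2 ** 31)
                )
            model = fastica(
                data, q, seed=rs, nonlinearity=nonlinearity,
                max_iter=max_iter, tol=tol,
            )
            if not model.converged:
                warnings.warn(
                    f"icasso: run {run} at order {q} did not converge; excluded",
                    RuntimeWarning,
                )
                continue
            pooled.append(model.sources)
        if not pooled:
            rows.append((q, -np.inf, -np.inf, np.inf, np.inf))
            continue
        P = np.vstack(pooled)
        dis = 1.0 - np.abs(np.corrcoef(P))
        np.fill_diagonal(dis, 0.0)
        dis = np.clip(dis, 0.0, None)
        labels = fcluster(
            linkage(squareform(dis, checks=False), method="average"),
            q, criterion="maxclust",
        )
        iq = _stability_indices(P, labels)
        q25, q75 = np.percentile(iq, [25, 75])
        rows.append((q, float(iq.mean()), float(np.median(iq)), float(iq.std()),
                     float(q75 - q25)))
    detail = pd.DataFrame(rows, columns=["order", "mean_iq", "median_iq", "std_iq", "iqr_iq"])
    usable = detail[np.isfinite(detail["mean_iq"])]
    if usable.empty:
        raise RuntimeError("no candidate order produced converged runs")
    best = usable.sort_values(
        ["mean_iq", "std_iq", "iqr_iq"], ascending=[False, True, True], kind="stable"
    ).iloc[0]
    scores = detail["mean_iq"].to_numpy()
    keep = np.isfinite(scores)
    return OrderEstimate(
        "icasso",
        [c for c, f in zip(candidates, keep) if f],
        scores[keep],
        int(best["order"]),
        detail=detail,
    )
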