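"""Independent reference implementations used only to check the package."""

import numpy as np


def brute_force_rotation_unmixing(X: np.ndarray, n_angles: int = 1800):
    """Exhaustive unmixing of a 2-channel mixture by whitened-rotation search.

    Whitens X, then grid-searches the single rotation angle in [0, pi/2)
    (the residual ambiguity after whitening, up to permutation/sign)
    maximizing the sum of absolute excess kurtoses of the rotated rows.
    Returns the composite 2 x 2 unmixing matrix.
    """
    X = np.asarray(X, float)
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T / X.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    K = (evecs / np.sqrt(evals)).T
    Z = K @ Xc
    best, best_theta = -np.inf, 0.0
    thetas = np.linspace(0.0, np.pi / 2, n_angles, endpoint=False)
    for start in range(0, n_angles, 200):
        th = thetas[start:start + 200]
        c, s = np.cos(th)[:, None], np.sin(th)[:, None]
        y1 = c * Z[0] + s * Z[1]
        y2 = -s * Z[0] + c * Z[1]
        k = (np.abs((y1 ** 4).mean(axis=1) - 3.0)
             + np.abs((y2 ** 4).mean(axis=1) - 3.0))
        j = int(np.argmax(k))
        if k[j] > best:
            best, best_theta = k[j], th[j, 0] if th.ndim > 1 else th[j]
    ct, st = np.cos(best_theta), np.sin(best_theta)
    R = np.array([[ct, st], [-st, ct]])
    return R @ K


def flood_fill_clusters(supra: np.ndarray) -> list:
    """Connected components of a boolean grid by explicit BFS flood fill.

    8-connectivity in 2D (all neighbors differing by at most 1 per axis).
    Returns a list of sets of coordinate tuples.
    """
    supra = np.asarray(supra, bool)
    seen = np.zeros_like(supra)
    clusters = []
    offsets = [
        d for d in np.ndindex(*(3,) * supra.ndim)
        if any(o != 1 for o in d)
    ]
    offsets = [tuple(o - 1 for o in d) for d in offsets]
    for idx in zip(*np.nonzero(supra)):
        if seen[idx]:
            continue
        queue, comp = [idx], set()
        seen[idx] = True
        while queue:
            cur = queue.pop()
            comp.add(cur)
            for off in offsets:
                nb = tuple(c + o for c, o in zip(cur, off))
                if any(c < 0 or c >= s for c, s in zip(nb, supra.shape)):
                    continue
                if supra[nb] and not seen[nb]:
                    seen[nb] = True
                    queue.append(nb)
        clusters.append(comp)
    return clusters
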