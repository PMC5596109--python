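"""Statistical parametric maps and cluster-thresholded functional networks.

A feature map becomes an SPM by voxelwise z-scoring (population sd over the
in-mask voxels); a delivered network is the SPM thresholded one-sided at
z >= z_threshold with connected clusters smaller than min_cluster removed
(8-connectivity in 2D, 26-connectivity in 3D). Defaults z = 2.0 and
10 voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import unmask

__all__ = ["SPMap", "BFNMap", "zscore_map", "threshold_clusters"]


@dataclass
class SPMap:
    """z-scored spatial map (mean 0, population sd 1 over the mask)."""

    z_values: np.ndarray
    component: int | None = None
    source_level: str | None = None
    shape: tuple | None = None
    mask: np.ndarray | None = None


@dataclass
class BFNMap:
    """Thresholded, cluster-size-controlled z-map."""

    z_values: np.ndarray            # thresholded (zeros below threshold / in small clusters)
    z_threshold: float
    min_cluster_size: int
    labels: np.ndarray              # same geometry as z_values, 0 = background
    cluster_sizes: dict = field(default_factory=dict)
    empty: bool = False

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.z_values))


def zscore_map(values: np.ndarray, mask: np.ndarray | None = None, **meta) -> SPMap:
    """z-score a map over its in-mask voxels (population sd)."""
    v = np.asarray(values, dtype=float).ravel()
    if mask is not None:
        sel = np.asarray(mask, bool).ravel()
        x = v[sel]
    else:
        sel = None
        x = v
    sd = x.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
        raise ValueError("constant map cannot be z-scored")
    z = np.zeros_like(v)
    if sel is None:
        z = (v - x.mean()) / sd
    else:
        z[sel] = (x - x.mean()) / sd
    return SPMap(z_values=z, mask=mask if mask is None else np.asarray(mask, bool),
                 **meta)


def threshold_clusters(
    spm,
    z_threshold: float = 2.0,
    min_cluster: int = 10,
    shape: tuple | None = None,
    mask: np.ndarray | None = None,
) -> BFNMap:
    """One-sided threshold at ``z_threshold`` then drop clusters < ``min_cluster``.

    ``spm`` may be an :class:`SPMap` or a raw array. Flat maps are embedded
    into ``shape`` (or the SPMap's mask geometry) before labeling; without
    spatial information a 1D chain topology is used.
    """
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")
    if not np.isfinite(z_threshold):
        raise ValueError("z_threshold must be finite")
    if isinstance(spm, SPMap):
        z = spm.z_values
        shape = shape or spm.shape
        mask = mask if mask is not None else spm.mask
    else:
        z = np.asarray(spm, dtype=float)
    flat_input = z.ndim == 1
    if flat_input and mask is not None:
        grid = unmask(z, np.asarray(mask, bool))
    elif flat_input and shape is not None:
        grid = z.reshape(shape)
    else:
        grid = z
    supra = grid >= z_threshold
    structure = np.ones((3,) * grid.ndim, dtype=bool)
    labels, n = ndimage.label(supra, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = {lab for lab, sz in zip(range(1, n + 1), sizes) if sz >= min_cluster}
    out = np.where(np.isin(labels, list(keep)), grid, 0.0)
    labels = np.where(np.isin(labels, list(keep)), labels, 0)
    # relabel surviving clusters 1..K in a stable order
    relabeled = np.zeros_like(labels)
    cluster_sizes = {}
    for new, lab in enumerate(sorted(keep), start=1):
        sel = labels == lab
        relabeled[sel] = new
        cluster_sizes[new] = int(sel.sum())
    return BFNMap(
        z_values=out,
        z_threshold=float(z_threshold),
        min_cluster_size=int(min_cluster),
        labels=relabeled,
        cluster_sizes=cluster_sizes,
        empty=not cluster_sizes,
    )
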