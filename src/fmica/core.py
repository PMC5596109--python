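"""Shared containers used across the hierarchy.

Two objects travel between modules: :class:`SubjectData`, one subject's
masked time x voxel matrix, and :class:`FeatureMapSet`, a stack of spatial
maps (components x voxels) tagged with the hierarchy level it belongs to.
Feature maps are the only currency exchanged between the levels: the raw
4D data is touched exactly once, at the first (single-subject) level.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Any

import numpy as np

#: Hierarchy levels a feature-map set can live at.
LEVELS = (
    "subject",
    "intragroup",
    "intergroup",
    "intragroup_specific",
    "subject_specific",
)


@dataclass
class SubjectData:
    """One subject's fMRI run, flattened to a time x voxel matrix.

    Parameters
    ----------
    data : ndarray, shape (T, V)
        BOLD signal for the V in-mask voxels at T time points.
    mask : ndarray of bool
        Spatial mask; ``mask.sum() == V``. May be given flat or with the
        spatial ``shape``.
    shape : tuple of int
        Spatial grid shape (2D for simulated slices, 3D for volumes).
    tr : float
        Repetition time in seconds.
    subject_id, dataset_id : str
        Identifiers used for provenance through the hierarchy.
    affine : ndarray, shape (4, 4), optional
        Voxel-to-world affine, carried through untouched for write-back.
    """

    data: np.ndarray
    mask: np.ndarray
    shape: tuple
    tr: float
    subject_id: str
    dataset_id: str
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.shape = tuple(int(s) for s in self.shape)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2D time x voxel matrix")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if int(self.mask.sum()) != self.data.shape[1]:
            raise ValueError(
                f"mask selects {int(self.mask.sum())} voxels but data has "
                f"{self.data.shape[1]} columns"
            )
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class FeatureMapSet:
    """A components x voxels stack of spatial maps at one hierarchy level.

    ``maps[j]`` is the j-th spatial component over the in-mask voxels.
    ``level`` must be one of :data:`LEVELS`; subject-level sets carry both
    ``dataset_id`` and ``subject_id``, intergroup sets carry neither.
    """

    maps: np.ndarray
    level: str
    dataset_id: str | None = None
    subject_id: str | None = None
    mask: np.ndarray | None = None
    shape: tuple | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("maps contain non-finite values")
        zero_rows = np.where(~self.maps.any(axis=1))[0]
        if zero_rows.size:
            raise ValueError(f"all-zero map rows: {zero_rows.tolist()}")
        if self.level in ("subject", "subject_specific"):
            if self.dataset_id is None or self.subject_id is None:
                raise ValueError(f"{self.level} sets require dataset_id and subject_id")
        elif self.level in ("intragroup", "intragroup_specific"):
            if self.dataset_id is None:
                raise ValueError(f"{self.level} sets require dataset_id")
        elif self.level == "intergroup":
            if self.dataset_id is not None or self.subject_id is not None:
                raise ValueError("intergroup sets carry no dataset/subject ids")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if int(self.mask.sum()) != self.maps.shape[1]:
                raise ValueError("mask voxel count does not match map width")

    @property
    def order(self) -> int:
        """Number of components in the set."""
        return self.maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.maps.shape[1]

    def content_hash(self) -> str:
        """SHA-256 of the map values (reproducibility checks)."""
        return hashlib.sha256(np.ascontiguousarray(self.maps).tobytes()).hexdigest()


def unmask(values: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Embed a masked vector (or stack of vectors) back into the full grid."""
    mask = np.asarray(mask, dtype=bool)
    values = np.asarray(values)
    if values.ndim == 1:
        out = np.full(mask.shape, fill, dtype=float)
        out[mask] = values
        return out
    out = np.full((values.shape[0],) + mask.shape, fill, dtype=float)
    out[:, mask] = values
    return out
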