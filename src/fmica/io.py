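"""NIfTI / YAML / JSON I/O for subjects, feature maps and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .core import FeatureMapSet, SubjectData, unmask

__all__ = [
    "SubjectData",
    "load_subject",
    "save_subject",
    "save_maps",
    "load_maps",
    "save_truth",
    "load_truth",
    "load_manifest",
]


def _spatial(img_shape):
    # drop trailing singleton axes so a (X, Y, 1) slice round-trips as 2D
    shape = tuple(img_shape)
    while len(shape) > 2 and shape[-1] == 1:
        shape = shape[:-1]
    return shape


def load_subject(
    nifti_path,
    mask_path=None,
    tr: float | None = None,
    subject_id: str = "sub-01",
    dataset_id: str = "dataset",
) -> SubjectData:
    """Load a 4D NIfTI volume as a masked time x voxel matrix.

    The default mask keeps voxels with nonzero temporal variance. TR is
    read from the header zooms unless given.
    """
    img = nib.load(str(nifti_path))
    vol = np.asarray(img.get_fdata())
    if vol.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {vol.shape}")
    if np.isnan(vol).all(axis=-1).any():
        raise ValueError("volume contains NaN-only voxels")
    spatial = vol.shape[:3]
    data = vol.reshape(-1, vol.shape[3]).T    # time x voxel (full grid)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).get_fdata()) > 0
        if mask.shape != spatial:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume {spatial}"
            )
    else:
        mask = (data.std(axis=0) > 0).reshape(spatial)
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    shape = _spatial(spatial)
    return SubjectData(
        data=data[:, mask.ravel()],
        mask=mask.reshape(shape),
        shape=shape,
        tr=tr,
        subject_id=subject_id,
        dataset_id=dataset_id,
        affine=img.affine,
    )


def _to_4d(mask: np.ndarray, rows: np.ndarray) -> np.ndarray:
    grid = unmask(rows, mask)                  # (k, *shape)
    vol = np.moveaxis(grid, 0, -1)             # (*shape, k)
    while vol.ndim < 4:
        vol = vol[..., None, :] if vol.ndim == 3 else vol[..., None]
    return vol


def save_subject(subject: SubjectData, path) -> Path:
    """Write a SubjectData back to a 4D NIfTI (inverse of load_subject)."""
    path = Path(path)
    vol = _to_4d(subject.mask, subject.data)
    img = nib.Nifti1Image(vol, subject.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (subject.tr,))
    nib.save(img, str(path))
    return path


def save_maps(fset: FeatureMapSet, out_path, affine=None, bfns=None) -> Path:
    """Write a feature-map set as one 4D NIfTI plus a JSON sidecar."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    mask = fset.mask if fset.mask is not None else np.ones(
        fset.shape or (fset.n_voxels,), dtype=bool
    )
    vol = _to_4d(mask, fset.maps.astype(np.float32))
    nib.save(nib.Nifti1Image(vol, np.eye(4) if affine is None else affine),
             str(out_path))
    sidecar = {
        "level": fset.level,
        "dataset_id": fset.dataset_id,
        "subject_id": fset.subject_id,
        "order": int(fset.order),
        "provenance": _jsonable(fset.provenance),
    }
    if bfns is not None:
        sidecar["bfn"] = [
            {
                "z_threshold": b.z_threshold,
                "min_cluster_size": b.min_cluster_size,
                "n_voxels": b.n_voxels,
                "cluster_sizes": b.cluster_sizes,
            }
            for b in bfns
        ]
    out_path.with_suffix("").with_suffix(".json").write_text(
        json.dumps(sidecar, indent=2)
    )
    return out_path


def load_maps(path) -> FeatureMapSet:
    """Reload a feature-map set written by :func:`save_maps`."""
    path = Path(path)
    vol = np.asarray(nib.load(str(path)).get_fdata())
    shape = _spatial(vol.shape[:-1])
    maps = np.moveaxis(vol, -1, 0).reshape(vol.shape[-1], -1)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return FeatureMapSet(
        maps=maps,
        level=meta["level"],
        dataset_id=meta.get("dataset_id"),
        subject_id=meta.get("subject_id"),
        mask=np.ones(shape, dtype=bool),
        shape=shape,
        provenance=meta.get("provenance", {}),
    )


def save_truth(truth, path) -> Path:
    """Persist simulator ground truth as a compressed array container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        group_sources=truth.group_sources,
        subject_sources=truth.subject_sources,
        timecourses=truth.timecourses,
        variation_params=truth.variation_params,
        noise_sd=truth.noise_sd,
        seed_used=truth.seed_used,
        shape=np.asarray(truth.shape),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_truth(path):
    from .synthetic_data import SimTruth

    with np.load(Path(path), allow_pickle=False) as z:
        return SimTruth(
            group_sources=z["group_sources"],
            subject_sources=z["subject_sources"],
            timecourses=z["timecourses"],
            variation_params=z["variation_params"],
            noise_sd=z["noise_sd"],
            seed_used=int(z["seed_used"]),
            shape=tuple(int(s) for s in z["shape"]),
        )


def load_manifest(path) -> list[list[SubjectData]]:
    """Load datasets from a YAML manifest.

    Layout::

        datasets:
          - id: rest_s1
            tr: 2.0
            subjects:
              - id: sub-01
                path: sub01.nii.gz
                mask: mask.nii.gz   # optional
    """
    spec = yaml.safe_load(Path(path).read_text())
    root = Path(path).parent
    datasets = []
    for ds in spec["datasets"]:
        subs = []
        for sub in ds["subjects"]:
            subs.append(
                load_subject(
                    root / sub["path"],
                    mask_path=(root / sub["mask"]) if sub.get("mask") else None,
                    tr=ds.get("tr"),
                    subject_id=str(sub["id"]),
                    dataset_id=str(ds["id"]),
                )
            )
        datasets.append(subs)
    return datasets


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return None  # drop heavy tables from sidecars
    return obj
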