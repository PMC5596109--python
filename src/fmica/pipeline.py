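"""The hierarchical pipeline: three ICA levels over feature maps plus the
two constrained re-estimations.

Level 1 decomposes each subject's time x voxel data into spatial
independent components (the feature maps).  Level 2 decomposes the
row-concatenation of a dataset's feature maps into intragroup maps.  With
m >= 2 datasets, level 3 decomposes the concatenated intragroup maps into
intergroup maps; constrained ICA then re-estimates intragroup-specific
maps (references = intergroup maps) and subject-specific maps (references
= intragroup-specific or intergroup maps).  With a single dataset the
third level and the intragroup-specific stage are skipped and the
intragroup maps serve directly as the subject-level references.

Feature maps are treated as observation rows over voxel samples at levels
2 and 3 (feature-based ICA); PCA reduction of the rows to the target order
precedes the fixed-point iteration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatureMapSet, SubjectData
from .ica import estimate_order_laplace, fastica, icasso_select, mean_order
from .icar import icar_extract, make_references
from .spm import threshold_clusters, zscore_map

__all__ = [
    "FmicaConfig",
    "FmicaResult",
    "Aggregate",
    "common_mask",
    "first_level",
    "aggregate",
    "second_level",
    "third_level",
    "reestimate_specific",
    "run_fmica",
]


def _child_seed(*keys) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2 ** 31))


@dataclass
class FmicaConfig:
    """Tunable knobs of one hierarchy run.

    ``first_order``/``second_order``/``third_order`` override the order
    rules (Laplace evidence / mean order / average-or-ICASSO) when set.
    ``subject_ref_source`` picks the references for the subject-specific
    re-estimation: 'auto' uses the intragroup-specific maps when m >= 2
    and the intragroup maps when m == 1; 'intergroup' forces the
    intergroup maps.
    """

    first_order: int | None = None
    second_order: int | None = None
    third_order: int | None = None
    same_subjects: bool = True
    subject_ref_source: str = "auto"     # auto | intragroup_specific | intergroup
    z_ref: float = 1.0
    xi: float = -0.5
    icar_pin: float = 0.98
    bfn_z: float = 2.0
    bfn_min_cluster: int = 10
    nonlinearity: str = "tanh"
    max_order: int | None = None
    icasso_runs: int = 20
    compute_bfns: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.subject_ref_source not in ("auto", "intragroup_specific", "intergroup"):
            raise ValueError(f"bad subject_ref_source {self.subject_ref_source!r}")


@dataclass
class Aggregate:
    """Row-stacked feature maps with per-row provenance."""

    maps: np.ndarray
    provenance: pd.DataFrame        # columns: set_index, dataset_id, subject_id, component
    mask: np.ndarray | None = None
    shape: tuple | None = None

    def row_origin(self, row: int) -> dict:
        return self.provenance.iloc[row].to_dict()


@dataclass
class FmicaResult:
    """Everything one hierarchy run delivers."""

    subject_sets: dict              # (dataset_id, subject_id) -> FeatureMapSet
    intragroup: dict                # dataset_id -> FeatureMapSet
    intergroup: FeatureMapSet | None
    intragroup_specific: dict       # dataset_id -> FeatureMapSet (empty when m == 1)
    subject_specific: dict          # (dataset_id, subject_id) -> FeatureMapSet
    bfns: dict                      # same keys, level-prefixed -> list[BFNMap]
    orders: dict
    config: FmicaConfig
    mask: np.ndarray | None = None
    shape: tuple | None = None
    errors: list = field(default_factory=list)

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for name, group in (
            ("subject", self.subject_sets),
            ("intragroup", self.intragroup),
            ("intragroup_specific", self.intragroup_specific),
            ("subject_specific", self.subject_specific),
        ):
            for key in sorted(group, key=str):
                h.update(f"{name}:{key}".encode())
                h.update(group[key].content_hash().encode())
        if self.intergroup is not None:
            h.update(b"intergroup")
            h.update(self.intergroup.content_hash().encode())
        return h.hexdigest()


def common_mask(subjects) -> np.ndarray:
    """Intersection of per-subject valid-voxel (nonzero variance) masks."""
    out = None
    for s in subjects:
        m = np.zeros(s.mask.shape, dtype=bool)
        m[s.mask] = s.data.std(axis=0) > 0
        out = m if out is None else (out & m)
    if out is None or not out.any():
        raise ValueError("common mask is empty")
    return out


def _restrict(subject: SubjectData, mask: np.ndarray) -> np.ndarray:
    """Subject's data columns restricted to a common mask (subset of its own)."""
    cols = mask[subject.mask.astype(bool)].ravel() if mask.shape == subject.mask.shape \
        else mask.ravel()[subject.mask.ravel()]
    return subject.data[:, cols]


def first_level(
    subjects,
    order_rule="laplace",
    seed: int = 0,
    nonlinearity: str = "tanh",
    max_order: int | None = None,
    mask: np.ndarray | None = None,
) -> list[FeatureMapSet]:
    """Per-subject spatial ICA; order from the Laplace evidence unless fixed.

    ``order_rule`` is 'laplace' or an integer override. Degenerate
    subjects are skipped with a warning (the returned list only contains
    successful decompositions).
    """
    sets = []
    for i, sub in enumerate(subjects):
        data = sub.data if mask is None else _restrict(sub, mask)
        try:
            if order_rule == "laplace":
                order = estimate_order_laplace(data, max_order=max_order).chosen
            else:
                order = int(order_rule)
            model = fastica(
                data, order, seed=_child_seed(seed, 1, i), nonlinearity=nonlinearity
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(
                f"first level: skipping {sub.dataset_id}/{sub.subject_id}: {exc}",
                RuntimeWarning,
            )
            continue
        sets.append(
            FeatureMapSet(
                maps=model.sources,
                level="subject",
                dataset_id=sub.dataset_id,
                subject_id=sub.subject_id,
                mask=mask if mask is not None else sub.mask,
                shape=sub.shape,
                provenance={
                    "order": order,
                    "order_rule": order_rule,
                    "converged": model.converged,
                    "n_iterations": model.n_iterations,
                    "seed": model.seed,
                },
            )
        )
    return sets


def aggregate(sets) -> Aggregate:
    """Row-concatenate feature-map sets, keeping a per-row provenance table."""
    sets = list(sets)
    if not sets:
        raise ValueError("no sets to aggregate")
    V = sets[0].n_voxels
    mask = sets[0].mask
    rows, prov = [], []
    for si, s in enumerate(sets):
        if s.n_voxels != V:
            raise ValueError("voxel dimension mismatch across sets")
        if (s.mask is None) != (mask is None) or (
            mask is not None and not np.array_equal(s.mask, mask)
        ):
            raise ValueError("mask mismatch across sets")
        rows.append(s.maps)
        for c in range(s.order):
            prov.append((si, s.dataset_id, s.subject_id, c))
    return Aggregate(
        maps=np.vstack(rows),
        provenance=pd.DataFrame(
            prov, columns=["set_index", "dataset_id", "subject_id", "component"]
        ),
        mask=mask,
        shape=sets[0].shape,
    )


def second_level(
    aggregated,
    subject_orders=None,
    order: int | None = None,
    seed: int = 0,
    dataset_id: str | None = None,
    nonlinearity: str = "tanh",
) -> FeatureMapSet:
    """Intragroup ICA on the aggregated feature maps of one dataset."""
    agg = aggregated if isinstance(aggregated, Aggregate) else Aggregate(
        maps=np.atleast_2d(np.asarray(aggregated, float)),
        provenance=pd.DataFrame(),
    )
    if order is None:
        if subject_orders is None:
            raise ValueError("need subject_orders or an explicit order")
        order = mean_order(subject_orders)
    if agg.maps.shape[0] < order:
        raise ValueError("aggregated rows fewer than the target order")
    if dataset_id is None:
        ids = set(agg.provenance.get("dataset_id", pd.Series(dtype=object)).dropna())
        dataset_id = ids.pop() if len(ids) == 1 else "group"
    model = fastica(agg.maps, order, seed=_child_seed(seed, 2), nonlinearity=nonlinearity)
    return FeatureMapSet(
        maps=model.sources,
        level="intragroup",
        dataset_id=dataset_id,
        mask=agg.mask,
        shape=agg.shape,
        provenance={
            "order": order,
            "converged": model.converged,
            "n_iterations": model.n_iterations,
            "seed": model.seed,
        },
    )


def third_level(
    intragroup_sets,
    same_subjects: bool = True,
    order: int | None = None,
    n_runs: int = 20,
    seed: int = 0,
    nonlinearity: str = "tanh",
) -> FeatureMapSet:
    """Intergroup ICA across datasets' intragroup maps.

    Order rule: the rounded average of the intragroup component counts when
    the datasets are sessions of the same subjects, otherwise ICASSO
    stability selection over [min(counts), max(counts)].
    """
    sets = list(intragroup_sets)
    if len(sets) < 2:
        raise ValueError("third level needs m >= 2 datasets; use the m=1 path")
    counts = [s.order for s in sets]
    agg = aggregate(sets)
    prov = {"counts": counts}
    if order is not None:
        prov["order_rule"] = "fixed"
    elif same_subjects:
        order = mean_order(counts)
        prov["order_rule"] = "average_order"
    else:
        est = icasso_select(
            agg.maps, min(counts), max(counts), n_runs=n_runs,
            seed=_child_seed(seed, 3, 0), nonlinearity=nonlinearity,
        )
        order = est.chosen
        prov["order_rule"] = "icasso"
        prov["candidates"] = est.candidates
        prov["stability"] = est.detail
    model = fastica(agg.maps, order, seed=_child_seed(seed, 3, 1), nonlinearity=nonlinearity)
    prov.update(
        order=order, converged=model.converged,
        n_iterations=model.n_iterations, seed=model.seed,
    )
    return FeatureMapSet(
        maps=model.sources, level="intergroup",
        mask=agg.mask, shape=agg.shape, provenance=prov,
    )


_SPECIFIC_LEVEL = {"subject": "subject_specific", "intragroup": "intragroup_specific"}


def reestimate_specific(
    target_sets,
    reference_maps,
    z_ref: float = 1.0,
    xi: float = -0.5,
    pin: float = 0.98,
    seed: int = 0,
) -> list[FeatureMapSet | None]:
    """Constrained re-estimation of every target set against shared references.

    Output component j corresponds to reference j.  A failing target is
    reported with a warning and yields None; the batch continues.
    """
    ref_level = reference_maps.level if isinstance(reference_maps, FeatureMapSet) else "intragroup"
    refs = make_references(reference_maps, z_ref=z_ref, source_level=ref_level,
                           closeness_xi=xi)
    out = []
    for t, target in enumerate(target_sets):
        level = _SPECIFIC_LEVEL.get(target.level)
        if level is None:
            raise ValueError(f"cannot re-estimate a {target.level!r} set")
        try:
            fm = icar_extract(
                target, refs, seed=_child_seed(seed, 4, t), pin=pin,
                level=level, dataset_id=target.dataset_id,
                subject_id=target.subject_id,
            )
            fm.mask, fm.shape = target.mask, target.shape
            out.append(fm)
        except (ValueError, np.linalg.LinAlgError) as exc:
            warnings.warn(f"re-estimation failed for target {t}: {exc}", RuntimeWarning)
            out.append(None)
    return out


def _bfns_for(fset: FeatureMapSet, config: FmicaConfig):
    maps_bfn = []
    for j in range(fset.order):
        spm = zscore_map(fset.maps[j], component=j, source_level=fset.level)
        maps_bfn.append(
            threshold_clusters(
                spm, z_threshold=config.bfn_z, min_cluster=config.bfn_min_cluster,
                shape=fset.shape, mask=fset.mask,
            )
        )
    return maps_bfn


def run_fmica(datasets, config: FmicaConfig | None = None) -> FmicaResult:
    """Run the full hierarchy on ``datasets`` (a list of SubjectData lists).

    Executes levels 1 -> 2 -> (3 when m >= 2) -> constrained re-estimation,
    converts delivered sets to thresholded networks, and returns a
    :class:`FmicaResult` carrying seeds, chosen orders and any per-unit
    errors.  Identical (datasets, config) reruns are bit-reproducible.
    """
    config = config or FmicaConfig()
    datasets = [list(ds) for ds in datasets]
    if not datasets or any(not ds for ds in datasets):
        raise ValueError("need m >= 1 datasets, each with >= 1 subject")
    m = len(datasets)
    all_subjects = [s for ds in datasets for s in ds]
    mask = common_mask(all_subjects)
    shape = all_subjects[0].shape
    errors: list = []
    orders: dict = {}

    subject_sets: dict = {}
    intragroup: dict = {}
    per_ds_sets = []
    for k, ds in enumerate(datasets):
        ds_id = ds[0].dataset_id
        sets = first_level(
            ds,
            order_rule="laplace" if config.first_order is None else config.first_order,
            seed=_child_seed(config.seed, 10, k),
            nonlinearity=config.nonlinearity,
            max_order=config.max_order,
            mask=mask,
        )
        if not sets:
            errors.append(f"dataset {ds_id}: no subject decomposed at level 1")
            per_ds_sets.append([])
            continue
        for s in sets:
            subject_sets[(s.dataset_id, s.subject_id)] = s
        per_ds_sets.append(sets)
        sub_orders = [s.order for s in sets]
        orders[("first", ds_id)] = sub_orders
        agg = aggregate(sets)
        ig = second_level(
            agg, subject_orders=sub_orders, order=config.second_order,
            seed=_child_seed(config.seed, 20, k), dataset_id=ds_id,
            nonlinearity=config.nonlinearity,
        )
        intragroup[ds_id] = ig
        orders[("second", ds_id)] = ig.order

    if not intragroup:
        raise RuntimeError("every dataset failed at the first two levels")

    intergroup = None
    intragroup_specific: dict = {}
    if m >= 2:
        ig_sets = [intragroup[ds[0].dataset_id] for ds in datasets
                   if ds[0].dataset_id in intragroup]
        intergroup = third_level(
            ig_sets, same_subjects=config.same_subjects, order=config.third_order,
            n_runs=config.icasso_runs, seed=_child_seed(config.seed, 30),
            nonlinearity=config.nonlinearity,
        )
        orders[("third", None)] = intergroup.order
        specific = reestimate_specific(
            ig_sets, intergroup, z_ref=config.z_ref, xi=config.xi,
            pin=config.icar_pin, seed=_child_seed(config.seed, 40),
        )
        for s_in, s_out in zip(ig_sets, specific):
            if s_out is None:
                errors.append(f"intragroup-specific failed for {s_in.dataset_id}")
            else:
                intragroup_specific[s_out.dataset_id] = s_out

    subject_specific: dict = {}
    for k, ds in enumerate(datasets):
        ds_id = ds[0].dataset_id
        sets = per_ds_sets[k]
        if not sets or ds_id not in intragroup:
            continue
        if m == 1:
            refs_maps = intragroup[ds_id]
        elif config.subject_ref_source == "intergroup":
            refs_maps = intergroup
        else:  # auto / intragroup_specific
            refs_maps = intragroup_specific.get(ds_id, intergroup)
        results = reestimate_specific(
            sets, refs_maps, z_ref=config.z_ref, xi=config.xi,
            pin=config.icar_pin, seed=_child_seed(config.seed, 50, k),
        )
        for s_in, s_out in zip(sets, results):
            if s_out is None:
                errors.append(
                    f"subject-specific failed for {s_in.dataset_id}/{s_in.subject_id}"
                )
            else:
                subject_specific[(s_out.dataset_id, s_out.subject_id)] = s_out

    bfns: dict = {}
    if config.compute_bfns:
        for ds_id, fset in intragroup.items():
            bfns[("intragroup", ds_id)] = _bfns_for(fset, config)
        if intergroup is not None:
            bfns[("intergroup", None)] = _bfns_for(intergroup, config)
        for ds_id, fset in intragroup_specific.items():
            bfns[("intragroup_specific", ds_id)] = _bfns_for(fset, config)
        for key, fset in subject_specific.items():
            bfns[("subject_specific",) + key] = _bfns_for(fset, config)

    return FmicaResult(
        subject_sets=subject_sets,
        intragroup=intragroup,
        intergroup=intergroup,
        intragroup_specific=intragroup_specific,
        subject_specific=subject_specific,
        bfns=bfns,
        orders=orders,
        config=config,
        mask=mask,
        shape=shape,
        errors=errors,
    )
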