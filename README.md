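# fmica

Hierarchical feature-map ICA for identifying brain functional networks
(BFNs) across multiple fMRI datasets.

## The problem

Group ICA of fMRI traditionally concatenates raw 4D time series across
subjects before decomposing them. That becomes awkward when datasets were
acquired with different repetition times, scanners, or session lengths,
and it scales poorly with cohort size. `fmica` instead performs all group
analysis on **feature maps**: each subject's data is reduced once, by
single-subject spatial ICA, to a small stack of component maps, and every
subsequent level of analysis operates only on maps. The result is a
four-level description of brain organization:

1. **subject** — per-subject independent component maps (the feature maps);
2. **intragroup** — ICA on the row-concatenated feature maps of one dataset;
3. **intergroup** — ICA on the concatenated intragroup maps of all datasets
   (only when two or more datasets are supplied);
4. **intragroup-specific / subject-specific** — constrained ICA (ICA with
   spatial references, as in GIG-ICA) re-estimates, for each dataset and
   each subject, the component closest to each group-level reference map.

## The model

Observed mixtures follow the linear ICA model `X = A S`, solved by
fixed-point negentropy maximization with symmetric decorrelation
(FastICA), giving `Y = W X`. Constrained re-estimation solves, per
reference map `r`,

```
maximize J(y)   subject to  eps(y, r) <= xi  and  E[y^2] = 1,
```

where `J(y)` is the negentropy contrast and `eps(y, r) = -|corr(y, r)|`
measures closeness to the reference. Model order is chosen by Minka's
Laplace-approximation evidence at the subject level, by the rounded mean
subject order at the intragroup level, and at the intergroup level by the
average intragroup order (same-subject sessions) or by ICASSO stability
selection over the intragroup order range. Delivered maps are z-scored
into statistical parametric maps and thresholded at `z >= 2.0` with an
8-connected minimum cluster size of 10 voxels.

A bundled simulator generates multi-subject 2D fMRI slices with known
ground truth (Gaussian-blob sources, block-design and event-driven
hemodynamic time courses, per-subject spatial variation, calibrated
contrast-to-noise ratio), so the whole hierarchy is testable end to end.

## Worked example

```python
import numpy as np
from fmica import (SimConfig, synthesize_dataset, run_fmica, FmicaConfig,
                   recovery_report)

config = SimConfig(seed=1)               # 20 subjects, 148x148, 12 sources
subjects, truth = synthesize_dataset(config)

result = run_fmica([subjects], FmicaConfig(first_order=13, second_order=13, seed=1))

rep = recovery_report(result.intragroup["sim"].maps, truth.group_sources)
print("intragroup-to-truth r:", np.round(rep.per_source_r, 4))
print(f"mean = {rep.mean:.4f}, sd = {rep.sd:.4f}")
```

prints

```
intragroup-to-truth r: [0.9918 0.9891 0.99   0.9898 0.9913 0.9905 0.9921 0.991  0.9909 0.9571
 0.9909 0.962 ]
mean = 0.9855, sd = 0.0122
```

i.e. the twelve intragroup maps recovered from noisy, spatially varying
subjects correlate with the ground-truth sources at r = 0.96–0.99 (the two
weakest values belong to the two task-modulated sources, whose shared
block-design time courses make them intrinsically hardest to separate).
Continuing,

```python
sub = result.subject_specific[("sim", "sub-01")]
r_sub = recovery_report(sub.maps, truth.subject_sources[0]).mean
r_ica = recovery_report(result.subject_sets[("sim", "sub-01")].maps,
                        truth.subject_sources[0]).mean
print(f"sub-01 mean r: guided {r_sub:.4f} vs plain ICA {r_ica:.4f}")

bfn = result.bfns[("intragroup", "sim")][0]
print(f"BFN 1: {len(bfn.cluster_sizes)} cluster(s), {bfn.n_voxels} voxels above z=2")
```

```
sub-01 mean r: guided 0.8904 vs plain ICA 0.8884
BFN 1: 1 cluster(s), 782 voxels above z=2
```

The reference-guided subject-specific maps track each subject's own
(spatially varied) sources better than standalone per-subject ICA — across
the 20 simulated subjects the guided estimate wins for every subject.

## Command line

```bash
fmica simulate --config sim.yaml --out sim/        # data + truth.npz + manifest
fmica run --manifest sim/manifest.yaml --seed 1 --out run/
fmica evaluate --result run/ --truth sim/truth.npz --report report.json
```

`fmica run` writes one 4D NIfTI per feature-map set (components along the
fourth axis), JSON sidecars with orders/seeds/convergence, and a
`report.json` with the chosen orders and a content hash that is identical
across reruns with the same manifest, config and seed.

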