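# Methods

## Model and procedure

`fmica` identifies brain functional networks at four levels using only
spatial feature maps as the currency between levels.

**Level 1 (subject).** Each subject's time x voxel matrix is centered,
PCA-whitened to the model order, and decomposed by fixed-point spatial
ICA (negentropy contrast, symmetric decorrelation). Rows of the input are
time points (observed mixtures); columns are voxels (samples). The
resulting component maps are the subject's feature maps. The assumption
is the standard spatial-ICA one: networks are spatially sparse/
non-Gaussian and mutually independent over voxels.

**Level 2 (intragroup).** All feature maps of one dataset are stacked row
wise and decomposed by the same ICA, now treating each map as one
observation over voxel samples (feature-based ICA). Because every subject
contributes its own maps rather than raw time series, datasets with
different TRs or lengths pose no alignment problem.

**Level 3 (intergroup).** With m >= 2 datasets the intragroup maps are
stacked and decomposed once more. With m = 1 this level is skipped and no
intergroup or intragroup-specific output exists.

**Constrained re-estimation.** Group-level maps serve as spatial
references for ICA with references: for each reference r, one component y
is extracted from a target map stack by maximizing the negentropy J(y)
subject to eps(y, r) <= xi and E[y^2] = 1, with eps(y, r) =
-|Pearson corr(y, r)|. Intragroup-specific maps re-estimate each
dataset's intragroup stack against the intergroup references;
subject-specific maps re-estimate each subject's feature maps against the
intragroup-specific references (m >= 2, configurable to intergroup) or
the intragroup references (m = 1). Output component j always corresponds
to reference j, which removes the component-permutation ambiguity within
the hierarchy.

**Delivery.** Every delivered map is z-scored over the common mask
(population sd) into a statistical parametric map, thresholded one-sided
at z >= 2.0, and cluster-filtered at a minimum of 10 voxels with
8-connectivity (2D) / 26-connectivity (3D).

## Model order rules

* *Subject level*: Minka's Laplace-approximation evidence on the
  eigenspectrum of the sample covariance, maximized over candidate orders.
  The spectrum is taken over the smaller matrix dimension (time), with
  voxels as samples. Verified in tests against an independent
  implementation of the same published formula.
* *Intragroup level*: arithmetic mean of the dataset's subject orders,
  rounded half-up (the rounding rule is a package choice; the mean itself
  is the prescribed rule).
* *Intergroup level*: rounded average of the intragroup component counts
  when the datasets are sessions of the same subjects; otherwise ICASSO
  stability selection over candidates from min to max of the counts.
  ICASSO here uses randomized restarts only (no bootstrap resampling):
  per candidate order, n_runs = 20 decompositions are pooled, clustered
  by 1 - |correlation| average-linkage into `order` clusters, and scored
  by the cluster stability index Iq = mean within-cluster similarity -
  mean between-cluster similarity; the chosen order maximizes mean Iq
  with smaller STD then smaller IQR as tie-breakers. Restart-only ICASSO
  discriminates best when the candidate range brackets the rank of the
  aggregated maps (over-splitting becomes unstable); with strong,
  well-conditioned noise subspaces all orders can look stable, a known
  limitation of restart-only stability analysis.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `z_ref` | 1.0 | z units | light threshold applied to z-scored reference maps; keeps plausibly active voxels steering the extraction |
| `xi` | -0.5 | closeness | user-level closeness bound: require \|corr(y, r)\| >= 0.5, else the component is flagged `constraint_violated` |
| `icar_pin` | 0.98 | fraction | adaptive constraint: the solution must retain at least this fraction of the best achievable \|corr\| with its reference (see below) |
| `bfn_z` | 2.0 | z units | SPM threshold for delivered networks |
| `bfn_min_cluster` | 10 | voxels | minimum surviving cluster size |
| `nonlinearity` | tanh | - | contrast derivative; G(u) = log cosh u (robust default), `pow3` available |
| fastica `tol` / `max_iter` | 1e-6 / 1000 | - | fixed-point stop rule on max change in \|<w_new, w_old>\| |

## The constrained-ICA solver

Each reference is solved independently (one-unit extraction), so
references never compete. In the whitened target space the correlation
with a reference is linear, corr(w'Z, r) = w'c with c = Z r_std / V, and
the maximal achievable correlation is ||c||. The unmixing vector is
initialized at c/||c|| (the projection of the reference onto the target
span — the best purely supervised estimate) and iterated with the
approximate-Newton negentropy step plus an augmented-Lagrangian pull
toward the reference whose multiplier grows while the closeness
constraint is violated.

The working closeness bound is adapted per reference:
`xi_eff = min(xi, -icar_pin * ||c||)`. This keeps the constraint active at
convergence, so negentropy refines the reference-guided estimate instead
of drifting to the nearest unconstrained ICA fixed point (which would
reproduce plain ICA and forfeit the benefit of the group information).
This is consistent with the constrained-ICA literature, where the
closeness threshold must sit between the target component's correlation
and the largest non-target correlation; pinning to 98% of the achievable
correlation implements that adaptively. The user-level `xi` remains the
absolute satisfiability test: a reference essentially uncorrelated with
the target span converges somewhere, fails `xi`, and is flagged.

Unit variance of extracted components is exact by construction (unit
vector in a whitened space, population convention). Components are
oriented to correlate positively with their reference; unconstrained ICA
components are oriented to positive skewness (activation maps are
right-skewed), with the largest-|value| voxel sign as fallback, and
ordered by variance explained in the original space.

## The simulator

The generator emulates SimTB-style 2D multi-subject fMRI: per subject,
`data = baseline + sum_k TC_k (x) source_k + noise` on a square grid.

* **Sources**: peak-normalized anisotropic Gaussian blobs on a seeded,
  jittered grid layout (12 sources on 148 x 148 by default). User-supplied
  source atlases are accepted wherever sources enter.
* **Time courses**: block design (24 s on / 24 s off, five blocks at
  TR = 2 s) for the two task-modulated sources (task event amplitude =
  task-to-unique ratio x unique amplitude: 4 x 0.2 and 2 x 0.4), plus
  Bernoulli unique events (p = 0.2 per TR; amplitude 1 for non-task
  sources), convolved with the canonical double-gamma HRF (peak 6 s,
  undershoot 16 s, ratio 6, sampled at TR). Each course is scaled so its
  peak equals baseline x PSC/100 with PSC ~ N(3, 0.25^2) % floored at
  0.5 %.
* **Subject variation**: each source is independently translated
  (sd 1.5 voxels), rotated (sd 3 deg) and scaled (sd 0.03) about its
  center of mass with bilinear interpolation, zero fill outside the grid.
* **Noise**: white Gaussian over the grid with sd set so that the sd of
  the mean-removed noise-free signal over in-brain voxels (union of
  source supports at 5 % of peak) divided by the noise sd equals the
  requested CNR (default 1). `cnr = inf` produces noiseless data.
* **Determinism**: a master seed spawns per-subject child seeds for
  variation, time courses and noise; identical configs reproduce
  bit-identical data and truth.

What the simulator does **not** emulate: 3D anatomy, physiological or
structured noise, motion, scanner drift, spatial autocorrelation of
noise, or hemodynamic variability across regions. Passing tests therefore
demonstrate correctness of the algorithmic chain under the stated
generative model, not performance on real fMRI.

A consequence of the printed task parameters worth knowing: both task
sources share the block regressor, so their time courses correlate at
~0.975. Subject-level PCA to order 13 then retains little of their
difference direction, which caps their group-level recovery near
r ~ 0.94-0.96 while all other sources recover at ~0.99. This ceiling is a
property of the data-generating conditions (verified by projecting the
ground truth onto the retained subspaces), not of the estimator.

## Numerical choices

* Whitening uses the population covariance and `eigh`; requested orders
  above the numerical rank are reduced with a warning; rank-0 input is an
  error.
* Laplace evidence candidates with non-finite scores are dropped; pure
  noise selects the smallest candidate.
* Degenerate (constant) maps raise errors in z-scoring, correlation and
  closeness, with a relative tolerance guard (sd <= 1e-12 x scale).
* Greedy template matching (descending |r| without replacement) is the
  default; Hungarian assignment is available (`method="optimal"`). On
  matrices with distinct entries both agree in tests.
* Two-sample contrasts use Welch's t-test (unequal variances) by default.
* mean-order rounding is half-up; ICASSO tie-breaks are lexicographic
  (mean Iq desc, STD asc, IQR asc).
* Batch error policy: one subject's failure never aborts a group stage;
  failures are warned about and recorded in `FmicaResult.errors`.
* Maps are float64 in memory and float32 on disk (NIfTI convention);
  affines are carried through untouched.

## Problem sizes used in validation

The validation suite runs the full study-scale replica (20 subjects,
148 x 148, 120 time points, orders fixed at 13) once, plus reduced
configurations (3-4 subjects, 24-36 voxel grids, 3-5 sources) for
structural and property tests; the FastICA-vs-rotation-search oracle uses
50 two-source mixtures of 20 000 samples, and the constrained-ICA
recovery check uses 20 five-source mixtures of 3 000 voxels. These sizes
were chosen so the whole suite completes in a few minutes while keeping
every statistical check at the scale its claim refers to.

## Known limitations

* Real-fMRI preprocessing (slice timing, realignment, normalization,
  smoothing) is out of scope; inputs are assumed preprocessed and
  co-registered.
* No anatomical labeling or atlas lookup of delivered networks.
* Restart-only ICASSO (see above) can be indifferent across orders on
  data whose noise subspace is stable; bootstrap resampling is not
  implemented.
* The subject-specific improvement from reference guidance assumes the
  group references are cleaner than single-subject decompositions; with
  very few subjects or very heterogeneous groups that premise weakens.
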