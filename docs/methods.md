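# Methods

## Scope and assumptions

`gpconf` models the conformational energy surface of **one** molecule with
fixed composition and fixed atom ordering. Every ensemble operation enforces
that contract (the `Ensemble` constructor rejects frames whose atom sequence
differs), because the descriptor below is *not* permutation-invariant: atom
`i` in one frame must be atom `i` in every frame. Energies are carried in
kJ/mol throughout; the constant 4.184 kJ/mol per kcal/mol is exposed for
reporting. Atom indices are 0-based in code and 1-based in files and reports,
following chemistry convention for constraint tables.

## Descriptor

A conformation (charges `Z`, coordinates `R` in Å) maps to the symmetric
matrix `M_ij = Z_i Z_j / ||R_i − R_j||` for `i ≠ j` and
`M_ii = 0.5 Z_i^2.4`; the strict lower triangle in row-major order is the
feature vector (length n(n−1)/2). The representation is invariant under rigid
rotation, translation and inversion (tested to 1e−10 under random transforms)
and strictly monotone in every pairwise distance. No sorting or eigenspectrum
trick is applied to gain permutation invariance — the fixed-atom-order
contract makes it unnecessary, and row-consistent entries keep the map from
torsion space to descriptor space smooth. An optional atom-subset mask lets
users restrict the matrix to selected atoms (e.g. heavy atoms only); an
optional per-dimension standardization helper exists but is off by default,
since preprocessing never changed validation results beyond their noise.

## Gaussian-process core

With kernel matrices `K` (train/train), `L` (train/test) and `M` (test/test):

    mean     = y_c + Lᵀ (K + λI)⁻¹ (y − y_c)
    variance = diag(M) − diag(Lᵀ (K + λI)⁻¹ L)

Implementation notes:

* **Kernel.** Linear (dot product) by default; a squared-exponential kernel
  with explicit length scale is available but brings no benefit on smooth
  conformer data, at the cost of one more hyperparameter.
* **Noise term in the variance.** The predictive variance deliberately
  excludes the observation-noise term λ: the adaptive gate compares test
  variances against training-point variances, so a constant additive offset
  would cancel; what matters is the epistemic (data-density) part.
* **Centering.** `y_c = 0` by default; `center=True` subtracts the training
  mean. With the linear kernel and no centering, a zero descriptor predicts
  0 — documented, and irrelevant in practice since descriptors are strictly
  positive.
* **Numerics.** `(K + λI)` is Cholesky-factorized; on failure a 1e−10 jitter
  is added once before raising with advice to use λ > 0. Predictive variances
  in [−1e−8, 0) are clipped to 0; anything more negative raises. The fitted
  model caches the factorization and the training-point variances.
* **λ selection.** Stratified 10-fold CV MAE over a logarithmic grid, default
  10⁻⁸…10⁴ with 13 points (the grid's extents are a package choice; ties
  break toward the smaller λ). The inner grid search solves every λ from one
  eigendecomposition per fold — via the d×d Gram matrix in the primal when
  the linear kernel has d < n, else via the n×n kernel matrix — which is
  algebraically identical to refitting per λ (tested against explicit
  refits).

## Validation

* **Stratified folds.** Samples are sorted by energy, cut into consecutive
  blocks of k, and each block's members are dealt to distinct folds in a
  seeded random order. Every fold then spans the whole energy range with
  sizes differing by at most one.
* **Metrics.** RMSE and MAE in kJ/mol; MAE(%) relative to the *training*
  portion's energy range; **R² is the squared Pearson correlation**, not the
  coefficient of determination — the two differ for biased predictors, and
  the squared correlation is the convention reported here. Undefined
  correlations (constant truth or prediction) surface as NaN rather than a
  fabricated number.
* **Nested CV.** For each of `reps` repetitions (seed + rep) and each outer
  fold, λ is re-selected by inner 10-fold CV *on the training portion only*,
  the model is fit there, and the held-out fold is scored with the training
  portion's range. Summaries report dispersion both over all k·reps fold
  reports and over repetition means, since the two differ.
* **y-randomization.** Two scrambling modes: labels shuffled as a block, or
  each descriptor column shuffled independently across samples (destroying
  the joint structure while preserving marginals — a whole-row shuffle would
  merely replay the label permutation). The identical CV protocol runs on
  scrambled data and the fold-level MAEs are compared with a two-sided
  Mann-Whitney U test (normal approximation with tie correction). A
  `permutation` hook allows forcing the identity permutation, in which case
  the scrambled run reproduces the real metrics exactly — a self-check of the
  protocol. The selected λ on scrambled data is reported too: scrambling
  should (and does) inflate the assumed noise level by orders of magnitude.

## Learning on the fly

The controller starts from an energy-stratified initial training set
(default 50 conformers; drawn from a caller-supplied pool — typically the
first MD run — or from the stream itself when its members carry reference
energies, else the first items are taken as-is). λ is selected once on the
initial set and then held fixed (`reoptimize_each` re-runs the grid search
after every retrain; per-step grid CV makes the pass quadratically more
expensive for little benefit on these data). For each stream item in order:

1. compute the predictive variance;
2. if κ > 0 and the variance is strictly below the empirical κ-quantile
   (linear-interpolation definition) of the *current* training points'
   variances, predict and move on;
3. otherwise call the oracle, append the result to the training set, refit,
   and recompute the threshold (the quantile is defined on the training data,
   which has just changed).

κ = 0 is interpreted as "no confidence region": everything is recomputed,
including items whose variance happens to undercut the smallest
training-point variance. Every refit is a from-scratch fit (no incremental
factor updates; an update scheme would have to reproduce the from-scratch
result to 1e−8 anyway, and fit times are negligible at these sizes).
With retraining disabled (`retrain=False`, analysis mode) the predicted sets
are nested in κ; full adaptive runs need not be monotone in κ because early
rejections reshape the training set. Exact duplicates of training points are
an edge case: their variance ties the training values exactly, so duplicates
of points at or above the κ-quantile are recomputed, not predicted — with a
strict `<` gate, "predict everything" holds only in the continuous-data sense.

The κ trade-off table runs one full pass per κ under a common seed and
initialization; for multi-run studies it can average over every ordering of
the runs (4! = 24 for four runs), with the initial pool always the first run
of the ordering.

## Constraint scoring

ROESY/NOE-style constraints are upper distance bounds classed strong/medium/
weak (< 2.5 / 3.5 / 5.0 Å). Group-to-group distances average over all
left×right proton pairs arithmetically (1, 3 or 9 pairs; the r⁻⁶ NOE average
is available as an option but plain averaging is the default convention
here). Satisfaction is strictly `distance < bound`; equality at the bound
fails. Constraints satisfied by every conformer of an ensemble, or by none,
carry no ranking information and are filtered before scoring, with a report
of what was dropped and why.

## Landscapes

Descriptors are projected onto the top two principal components (eigenvectors
of the empirical covariance, largest-|loading| entry forced positive so signs
are reproducible). Energies are smoothed onto a regular grid (default
200×200, data bounding box padded 5%) with the Nadaraya–Watson estimator
under a Gaussian kernel. Per-axis bandwidths follow the normal reference rule
`h = 1.06 σ m^(−1/5)`, multiplied by a smoothing factor (default 0.3, treated
as a plain bandwidth multiplier; locally adaptive bandwidths are not
implemented — a global rule is used instead). Smoothed values are convex
combinations of the data, hence never leave the observed energy range; grid
cells that no data point reaches are masked, not extrapolated. Rendering uses
a blue (low) to red (high) map over relative energies.

## Synthetic studies

The generator emulates the data situation the toolkit targets — several MD
runs of a few hundred relaxed conformers of one molecule, energies from an
expensive noisy reference — without any chemistry engine:

* **Molecule.** A 12-atom chain alternating C/H, bonds 1.5 Å, angles 111°,
  nine free backbone torsions; internal-to-Cartesian construction.
* **Surface.** Per-torsion cosine terms `A (1 + cos(mφ − γ))` with base
  amplitudes cycling 3–8 kJ/mol, multiplicities alternating 1 and 2 along the
  chain and amplitudes scaled by 1/m² (first harmonics set the basin
  structure; gentler second harmonics add curvature so that accuracy keeps
  improving with training-set size instead of saturating immediately), plus a
  Lennard-Jones term (ε = 0.3 kJ/mol, σ = 2.5 Å) over atom pairs ≥ 4 bonds
  apart, plus Gaussian observation noise (default σ = 0.5 kJ/mol) drawn from
  a stream seeded per conformer id, so repeated oracle queries agree as
  repeated reference calculations would.
* **Runs.** Four runs of 240 frames. Run r samples torsions from
  `Normal(bias_r, 0.2² rad²)`; biases offset each torsion from the extended
  chain (π) by a seeded choice from {−60°, 0, +60°}, pairwise distinct, so
  runs occupy different basins and training on one run generalizes worse
  than training on a pooled sample of equal size. Frames with a hard clash
  (< 0.5 Å) or any nonbonded contact under 2.0 Å are resampled within a
  bounded retry budget — relaxed reference snapshots contain no steric
  clashes. Everything is reproducible from the seeds; byte-identical XYZ
  output is tested.

What the generator does *not* emulate: real quantum-chemical physics,
time-correlated trajectory structure (frames are i.i.d. within a run),
conformer relaxation, ring topologies, or ROESY spectra of the toy molecule.
Tests passing on these data therefore show the machinery is correct and the
statistical patterns (sampling bias, learning curve, noise floor,
randomization collapse, variance gating) behave as designed — not that any
particular accuracy transfers to a given real molecule.

## Problem sizes and runtime choices

The default study (4 × 240 conformers, 66-dimensional descriptors) keeps the
full pipeline fast: nested 10×10 CV in seconds, the complete validation-plus-
adaptive recomputation (`scripts/acceptance.py`) in about a minute on one
CPU. The sampling experiments average over five study seeds; the adaptive
summary averages over all 24 run orderings. These sizes are package defaults
chosen to make the statistical patterns clearly resolvable at desk scale.

## Known limitations

* The descriptor requires fixed atom ordering; conformers from tools that
  renumber atoms must be remapped first.
* The linear-kernel GP extrapolates poorly outside the sampled basins — by
  design the variance gate exists to detect exactly that, but a κ close to 1
  will let marginal extrapolations through.
* R² as squared Pearson correlation can flatter a biased predictor; read it
  together with RMSE/MAE.
* The landscape smoother uses a single global bandwidth per axis; sharply
  uneven data densities over the projection will over-smooth dense regions
  or under-smooth sparse ones.
* Model serialization stores the training set (non-parametric model): archives
  grow with n.
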