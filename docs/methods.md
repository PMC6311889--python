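# Methods

## Overview

`dmnfuse` implements a three-stage analysis of resting-state fMRI cohorts
split into two clinical groups (e.g. early vs late mild cognitive
impairment):

1. **Seed-to-voxel connectivity.** For each of N seed regions (by default
   the four default-mode-network hubs MPFC, PCC, LLP, RLP) the mean BOLD
   series over a seed sphere is Pearson-correlated with every in-mask voxel
   series and Fisher-z transformed. This yields N connectivity maps per
   subject.
2. **Joint ICA fusion.** The selected seeds' maps are concatenated per
   subject into a joint feature (a row of `X`, M subjects x N·V voxels) and
   the linear model `X = A S` is fitted at model order K (default 8): `S`
   holds K spatially independent joint sources spanning all seed blocks, and
   row i of `A` is subject i's K-dimensional mixing-coefficient vector,
   shared by all blocks of each source.
3. **Classification.** An RBF-kernel SVM with Platt-calibrated probability
   output classifies the mixing coefficients, over repeated stratified
   splits (13 train / 5 test per class, 100 repeats by default). Every
   nonempty seed combination (15 for four seeds) is swept, and a combination
   is called *complementary* when its mean accuracy beats every proper
   sub-combination.

## Joint ICA estimation

`JointICA.fit` column-centers `X`, reduces the subject dimension to K by
economy SVD with whitening, and estimates the K x K unmixing matrix by
Infomax: stochastic natural-gradient ascent with the logistic nonlinearity,
random orthonormal initialization from the given seed, initial learning rate
1e-3 annealed by 0.9 whenever successive weight updates oscillate (angle
above 60 degrees, or a growing step norm), at most 512 passes, convergence
when the per-pass weight-change norm falls below 1e-7. Plain (non-extended)
Infomax is used; the spatial sources of interest are sparse, hence
super-Gaussian, which is the regime this variant handles. Non-convergence
is recorded (`converged_`, plus an `InfomaxWarning`) and the final iterate
returned. The mixing matrix is back-reconstructed through the whitening
pseudo-inverse, so `A S` equals the rank-K approximation of the centered
data exactly.

Two ICA ambiguities are fixed deterministically: each source row's
largest-magnitude entry is made positive, and sources are ordered by
decreasing variance of their mixing column. Both operations are idempotent.

Held-out subjects never touch the fit: their joint features are built with
the *training* cohort's block norms and projected by least squares onto the
fitted sources (`a = x S^+`). Applied to a training subject this reproduces
its mixing row up to the PCA truncation residual; at full order
(K = rank of the centered matrix, i.e. M-1) it is exact to 1e-6 relative.

Note that centering across M subjects leaves the joint feature matrix with
rank M-1; "full order" therefore means M-1, not M.

## Normalization

Each map is centered to zero mean across voxels, then every seed block is
divided by the training cohort's root-mean-square over that block, so all
blocks enter the decomposition with equal mean sum-of-squares (within 1e-9).
Without this, a seed whose maps happen to have larger variance would
dominate the joint decomposition.

## Classification protocol

Hyperparameters C (penalty) and g (RBF width) are selected by
cross-validated accuracy (default 5 folds) over log2-spaced grids with step
0.5 (defaults: C in 2^-5..2^15, g in 2^-15..2^3); ties resolve to the
smallest C, then the smallest g. The final SVM is refit on the whole
training set and a sigmoid `p = 1/(1+exp(A f + B))` is fitted to its
training decision values by Platt's smoothed-target maximum likelihood.
Accuracy thresholds the calibrated probability at 0.5 (test sets are
balanced, so overall accuracy equals balanced accuracy).

For every split the entire fusion stage — block norms and joint ICA — is
refit on the training subjects only; test subjects are projected onto the
training sources. A leakage test asserts that corrupting a test subject's
maps changes neither the training features nor the chosen hyperparameters.
The ROC is pooled over all splits' test probabilities and its AUC computed
by the trapezoidal rule (equal to the Mann-Whitney pair statistic). One
split sequence is shared by all seed combinations so their accuracies are
compared on identical partitions.

A comparison-only `fusion_mode="fit-once"` fits the decomposition on the
whole cohort once and slices its mixing rows per split. Test subjects then
influence the decomposition and normalization, so this mode leaks and is
never the default; it exists to quantify that optimism against the
per-split protocol.

All randomness flows from explicit integer seeds: the experiment master
seed drives the split sequence, and each split's ICA seed is derived from
(master seed, split index) via a seed sequence. Identical configurations
reproduce byte-identical output tables.

## Synthetic cohorts

The generator emulates the covariance structure that seed-based analysis
assumes. Each subject's volume is

    bold(v, t) = sum_k c_k a_k(v) s_k(t) + sigma eps(v, t)

with smooth unit-norm spatial loadings `a_k` (Gaussian-smoothed spheres,
smoothing sigma 1.2 voxels), AR(1) temporal courses `s_k` (coefficient 0.3,
unit marginal variance), per-subject couplings `c_k`, and white Gaussian
observation noise (`noise_sigma`, default 1). Component 0 is a shared
network containing all seed spheres; components 1..N are seed-specific
satellites centred on each seed, so different seeds produce overlapping but
distinct maps; further components are background blobs. The group contrast
shifts the couplings of selected components in group 2 by
`effect_size * noise_sigma`, split across components by `effect_weights`
(default: all on the shared component).

Couplings are drawn as `c_k ~ Normal(4.0, 0.8)`. The mean sets the
in-network correlation level: at coupling/noise = 4 the strongest in-network
voxels reach r ≈ 0.5, the level seed-based DMN maps typically show near the
hubs; the 20% relative spread reflects between-subject variability in
network strength. Because correlation maps are invariant to a joint
rescaling of couplings and noise, only these ratios and the series length
matter.

Default cohort dimensions follow the target study design: 18 subjects per
group, 130 retained time points. The default spatial grid is reduced to
20x24x20 for desk-scale work (the full 91x109x91 grid is supported through
the same configuration field). The generator refuses grids too small to
hold all seed spheres disjointly inside the brain mask.

What the generator does **not** emulate: hemodynamic response shape,
physiological (cardiac/respiratory) noise, head motion, scanner drift,
spatial autocorrelation of the noise, multi-site effects, or any nonlinear
BOLD physics. Passing tests therefore show the pipeline is correct and
well-calibrated under a linear mixture model with planted effects — not
that the planted effect sizes correspond to any real clinical contrast.

## Numerical choices

- Fisher z values are computed as `atanh(r)` with |r| clipped at 1 - 1e-7,
  so a voxel identical to the seed gets a large finite value instead of
  infinity. Zero-variance voxels get z = 0; a zero-variance seed series is
  an error.
- Seed spheres include voxels whose centers lie within the radius
  (radius 0 = a single voxel); mm-space seeds are mapped through the NIfTI
  affine.
- `rank_sources` uses the pooled-variance two-sample t statistic per mixing
  column; "most different" is the largest |t|, ties to the lower index.
- K above the numerical rank of the centered feature matrix is rejected.
- The most-different source's K-robustness (little change when the
  decomposition is refit at K = 6..16) is checked with the effect planted
  on one compact satellite network. When the effect sits on the multi-lobe
  shared network, high-order spatial ICA splits that network into
  sub-networks — the familiar subnetwork splitting of spatial ICA — and the
  single most-different map is then not comparable across K.

## Experiment sizes used by the test suite

The repeated-split experiments in the test suite run at desk scale, chosen
so the full suite completes on one CPU in minutes: spatial grid 12x14x12
(seed radius 1.2 voxels), 18+18 subjects, T = 130, hyperparameter grids
C in 2^0..2^3 and g in 2^-4..2^-1 (step 0.5), model order 8. Null
calibration uses 100 splits; the power curve uses 25 splits per effect
size. At this scale the dominant variance in null-cohort accuracy is the
chance group separation of the fixed 36-subject cohort itself (its standard
deviation across cohorts is about 0.05-0.1), which repeated splitting
cannot reduce; mean null accuracy is also mildly pessimistic (below 0.5),
the usual small-sample behaviour of repeated splits of one cohort.

The complementarity experiment plants half the effect on each of the two
lateral-parietal seeds' satellite components (LLP and RLP — a
mirror-symmetric pair, so neither satellite is favoured by the mask
geometry) and uses the weak-coupling regime
(`coupling_mean = 1.0`, `coupling_sd = 0.3`): there each single-seed map is
a noisy reading of its own satellite, so fusing the two seeds genuinely
integrates complementary measurements. In the strong-coupling regime the
single-seed maps are already near their ceiling and fusion has no headroom
— mirroring the observation that most seed combinations are *not*
complementary.

## Known limitations

- The Conn-style weighted GLM connectivity measure is reduced to its
  uniform-weight special case (plain Pearson + Fisher z); resting-state
  single-condition data makes the weights uniform, but any temporal
  filtering the original toolboxes apply is not reproduced.
- No nuisance regression or bandpass filtering; inputs are assumed
  preprocessed.
- Model-order selection (MDL/AIC) is out of scope; K is a parameter.
- Real-data accuracy levels are not reproducible from synthetic cohorts and
  are not targets of the test suite.
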