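# Methods

This note records the model as implemented, the defaults and why they were
chosen, what the synthetic phantoms do and do not emulate, and the numerical
decisions that matter when reading results.

## Joint model

A grey volume `g : R -> {0..Q-1}` (Q = 256) and label map
`m : R -> {0,1,2,3}` are modelled jointly as
`P(g,m) = P(g|m) P_sp(m) P_V(m)`.  Inference is MAP: an initial map from the
first two factors, then ICM over all three.  The Gibbs partition function is
never evaluated; ICM uses only local energy differences.

### First-order intensity model (LCDG)

`P(g|m)` factorizes over voxels with per-class conditional densities over
grey levels.  The brain histogram is fit by a signed mixture of discrete
Gaussians (DG): a DG is a continuous Gaussian integrated over unit bins with
the two edge bins absorbing the tails, so each component sums to one
exactly.  Fitting has three phases: (1) histogram-weighted EM for K = 4
dominant positive components, initialized deterministically at the
histogram's quantile positions; (2) the positive and negative parts of the
residual (empirical minus dominant mixture) are each approximated by up to 4
subordinate DGs, one seed component per local maximum of the part;
(3) joint EM modified for signed weights under `sum(w+) - sum(w-) = 1`.
A phase-3 step is accepted only if the sup-distance between model and
empirical density does not increase; the refinement trace is therefore
monotone and the procedure cannot diverge, at the cost of sometimes stopping
at the phase-2 solution.

Finalization merges an adjacent pair of dominant components only when
replacing the pair by a single moment-matched DG does not worsen the fit.
This collapses the symmetric splits EM produces when K exceeds the number of
real modes, while keeping genuinely distinct but heavily overlapping class
modes (the isointense GM/WM pair) separate — a rule based on mode separation
would merge those and break the three-class partition.

Component standard deviations are floored at 1 grey level: intensities are
integer-quantized, and a sub-bin sigma is not identifiable from the
histogram while making the likelihood pathologically sharp (a one-level
intensity shift would drive the true class's likelihood to the floor).

The partition into tissue classes places thresholds at the minima of the
fitted mixed density between consecutive dominant means (grid search over
grey levels); with 4 dominant modes and 3 classes, the adjacent pair of
modes with the smallest mean gap is grouped first.  Subordinate components
join the class of the nearest dominant mean.  Class densities are clipped at
zero and renormalized; classes are mean-ordered and mapped to CSF < GM < WM,
the T1 intensity ordering of both presets.

### Adaptive shape prior

For each brain voxel `v` the prior maps `v` into the atlas domain by the
affine transform from registration, centres a cube (initial 3³) there, and
pools — across *all* training subjects, whose intensities were first
histogram-matched to the test subject — the voxels inside the cube whose
grey level lies within ±τ (default 10) of `g_v`.  The label histogram of
the matches, normalized, is the voxel's prior.  If no voxel matches, the
cube grows by 2 per axis (all axes equally) and the search repeats up to
11³.  Fallback at the maximal cube: the label frequencies of *all* voxels in
the cube, ignoring intensity — spatially informed and never zero; a voxel
mapped entirely outside the atlas gets a pure background prior.  Non-integer
mapped positions are rounded to the nearest voxel.  The construction is
deterministic.

Log-probabilities are floored at 1e-10 (shared with the likelihood), so a
zero prior contributes −23.03 rather than −inf; a certain prior plus a
certain likelihood can outweigh a local Gibbs energy difference of up to
about 46.

### Higher-order MGRF

Clique families on the 26-neighbourhood: pairwise grouped by neighbour
distance {1, √2, √3} (3 + 6 + 4 undirected offset classes pooled into 3
families), 13 families of collinear triples `{p−d, p, p+d}` (one per unique
direction), and 3 families of planar 2×2 squares (xy, xz, yz).  Triple and
quad shapes are the main geometry choice the framework leaves open; the
collinear/planar forms capture strand continuity and local surface patches
and are swappable behind the `CliqueFamily` abstraction.  Potentials depend
only on the equality pattern of the clique's labels and are estimated
analytically from the configuration frequencies of the initial map (not the
training maps), with λ* pooled across the three quad families as a single
scalar.  Cliques touching background are excluded everywhere (statistics,
potentials, energies), so the spatial model is brain-only.  If every quad
frequency sits at its reference value the λ* ratio is 0/0; λ* is set to 0
with a warning.

Identity worth noting: `(F_eq4−1/8) + (F_eq3−1/2) + (F_eq2−3/8) = 0`
identically, so the printed form `V4:eq2 = λ*(F_eq2−3/8)` and the
antisymmetry form `V4:eq2 = −(V4:eq4+V4:eq3)` are the same number.

### ICM

Raster-order sweeps with in-place updates; each brain voxel moves to the
tissue label maximizing `log p(g_p|l) + log p_sp:p(l) + E_local(l)` and only
on strict improvement, so the global objective is non-decreasing and the
iteration terminates.  Defaults: at most 10 sweeps, stop when fewer than
1e-4 of brain voxels change.  Potentials are estimated once from the initial
map; per-sweep re-estimation exists behind a flag, default off.  The sweep
kernel is numba-compiled; a pure-Python `local_energy` is the reference the
kernel is tested against, and both are cross-checked against exhaustive
clique enumeration on small lattices.

### Registration and fusion

Prototype selection ranks training subjects by Pearson correlation over the
union brain mask.  Affine registration (12 DOF, composed T·R·Sh·S about the
volume centre) maximizes 64-bin joint-histogram mutual information over a
3-level coarse-to-fine pyramid with Powell's method; the identity is
returned if optimization fails to beat it.  The bin count, pyramid schedule
and optimizer are not dictated by the framework and are configurable.
Candidate maps from the top-3 prototypes are fused by per-voxel majority
vote, ties resolved by prototype rank.

### Preprocessing

GGMRF smoothing replaces each brain voxel by the grey level minimizing
`|q−g_p|^α + ρ^α Σ w_pr |q−g_r|^β` over its 26 nonzero neighbours
(α = 2, β = 1.01, ρ = 1, weights 1, 1/√2, 1/√3 by distance, 1 sweep by
default; the framework fixes none of these, so all are config).  The
update is exact discrete search over Q using precomputed power tables.
Updates run in raster order in place, i.e. coordinate descent on the global
objective with each neighbour pair counted once, which is therefore
non-increasing.  Smoothing is restricted to nonzero voxels: inputs are
skull-stripped by contract and smoothing across the brain edge would erode
the mask.  Bias-field correction and skull stripping are upstream external
steps; phantoms are generated already stripped.

Histogram equalization (used before the prior's intensity search) is exact
monotone CDF matching of the nonzero-voxel histograms; background voxels are
untouched and nonzero voxels stay nonzero.

## Phantoms

Phantoms are nested axis-aligned ellipsoids — outer CSF shell, GM cortex,
WM core, central CSF ventricle — at 18/56/75/88 % of the grid half-extent,
rendered with per-class Gaussian noise (Rician optional), an optional
degree-2 polynomial multiplicative bias field (mean 1, default amplitude 0),
and quantized to integer grey levels; background is exactly 0.  Presets:
`adult` means 60/110/170 with sigma 12 (well-separated modes) and `infant`
means 90/110/130 with sigma 15 (GM/WM Bhattacharyya overlap above 0.5 — the
isointense regime).  Training subjects warp the base labels by a small
random affine (|rotation| ≤ 4°, |scale−1| ≤ 0.03, |translation| ≤ 2 voxels,
|shear| ≤ 0.01) composed with a smoothed random displacement field (max 1
voxel), then re-render with independent noise; labels are carried by
nearest-neighbour interpolation.  Affine maps preserve ellipsoid nesting, so
only the elastic term can break it; magnitudes of at least half the minimum
inter-shell gap are rejected.

What the phantoms do *not* emulate: cortical folding, partial-volume
voxels, multi-modal contrasts, and — importantly — realistic inter-subject
anatomical variability, which the nesting constraint bounds to a few voxels.
Consequences for interpreting results are below.

## Problem sizes used by the test suite and acceptance script

Unit tests run on 16³–32³ grids; the clique machinery is verified exactly
against brute-force enumeration on lattices up to 8³.  The end-to-end adult
evaluation uses 64³ with 10 training subjects; the noiseless
self-segmentation limit uses 48³ with the subject's own copy as the single
prototype; the paired MGRF-order comparison uses 48³ with 8 training
subjects and 5 seeds, sharing all stages up to the initial map within each
pair.  LCDG recovery uses 2·10⁵ samples.

## Behaviour worth knowing

* **Self-segmentation exactness is curvature-limited.**  With zero noise
  and the subject's own copy as prototype, the pipeline reproduces the
  ground truth voxel-exactly at 48³.  On larger grids the analytic
  potentials saturate (V2 → 2, V3 → 4 as the boundary fraction shrinks) and
  the Gibbs preference for homogeneity at the sharpest structure (the
  ventricle tip, curvature radius ~6 voxels) approaches the maximum evidence
  the floored data terms can supply (≈ 46 in log units); at 64³ roughly two
  dozen tip voxels flip, leaving CSF Dice at 0.9996.  This is the model's
  known smoothness bias — thin, highly curved structures are eroded — not a
  numerical artifact.
* **The higher-order advantage is regime-dependent.**  Started from a poor,
  speckled initial map (intensity-only classification of isointense data),
  the 4th-order model repairs errors the pairwise model cannot (WM Dice
  0.89–0.93 vs 0.71–0.89 across seeds).  Started from the adaptive prior's
  already-accurate initial map on these phantoms, the extra smoothing
  instead erodes correct boundaries and the pairwise model ends ahead
  (median WM Dice 0.97 vs 0.93).  Because the phantoms' inter-subject
  variability is bounded by construction, their priors are far stronger
  than clinical atlases; passing phantom tests therefore demonstrates the
  machinery, not the clinical ranking of the two spatial models, and the
  acceptance script reports both regimes.

## Configuration

Every default above is reachable from one YAML file (see `brainseg.config`):
`preprocess.ggmrf.{alpha,beta,rho,neighbor_weights,n_iters}`,
`preprocess.skip_ggmrf`, `shape_prior.{tau,cube_init,cube_step,cube_max}`,
`lcdg.{k_dominant,max_subordinate,min_weight,tol,max_iters,sigma_floor}`,
`registration.{bins,levels,max_iters,xtol}`,
`icm.{max_sweeps,stop_fraction,reestimate_potentials}`,
`segmenter.{k_prototypes,mgrf_order,assume_aligned}`.
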