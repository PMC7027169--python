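# Methods

This note documents the model, its numerical realization, the parameters
that matter, what the synthetic fixtures do and do not emulate, and the
design choices that were genuinely open.

## Generative model and estimation

An atlas image `I : X -> R^N` on a regular world-coordinate grid is related
to an observed target `J : X -> R^M` through three nuisances estimated
jointly:

1. **Shape.** A diffeomorphism `phi` generated by integrating a
   time-varying velocity field (`d/dt phi_t = v_t(phi_t)`, `phi = phi_1`),
   composed with an affine map `A` (family selectable: rigid, similarity,
   affine).  The total pullback from target coordinates to atlas
   coordinates is `phi^-1(A^-1 x)`; the affine acts on the target side and
   the diffeomorphism lives in atlas space.  The ordering is a convention
   (the model is equally expressive either way) and is recorded in the
   transform sidecar.
2. **Contrast.** A polynomial `F_theta` of the atlas intensities, either
   `full` (all cross-channel monomials of total degree <= O; C(N+O, O)
   coefficients per output channel) or `separable` (one univariate
   polynomial per channel).  Order >= 2 expresses non-monotone intensity
   permutations; order 1 is the affine/NCC special case, and the test suite
   asserts the closed-form equivalence of its minimized matching term with
   `0.5 sigma_M^-2 ||J - Jbar||^2 (1 - rho^2)` to 1e-10.
3. **Censoring.** Each pixel carries a missing label selecting one of a
   small family of atlases: the deformed template ("matching") or constant
   images ("artifact", "background").  One or two constant classes are
   supported; more invites overfitting on piecewise-constant images, since
   a large enough constant family can explain the target without any
   registration.

Estimation alternates an E-step (Gaussian responsibilities with uniform
class priors, computed in the log domain with max-subtraction) with an
M-step that updates `theta` and the constant class means in closed form and
takes simultaneous backtracking gradient-descent steps on `v` and the
affine.  The velocity gradient is the classic optimality condition: the
residual, transported to time `t` by `phi_1 phi_t^-1`, weighted by the
transported matching posterior and Jacobian determinant, multiplied by the
gradient of the deformed (contrast-mapped) atlas, then smoothed with
`K = A^-1` — the Hilbert-space (Sobolev-preconditioned) descent direction.

### Objective bookkeeping and EM monotonicity

The matching term is discretized as a Riemann sum (pixel sum times voxel
volume); correspondingly the EM surrogate tracked per cycle is
`regularization - voxel_volume * sum_i log sum_c prior_c N(J_i; mean_c,
sigma_c^2)`.  With that weighting a full EM cycle cannot increase the
surrogate, *up to two float-level caveats*: the line search accepts steps
up to a 1e-10 relative slack, and the contrast solve carries a relative
ridge (below), so monotonicity is asserted to 1e-8 relative rather than
exactly.  Backtracking events are recorded in the objective trace.

## Numerical choices

* **Grids.** Voxel centers carry world coordinates (`origin + k *
  spacing`); channel axis last; slowest axis first.  All transforms act on
  world coordinates so multi-resolution images compose correctly.
* **Interpolation.** Multilinear, clamp-to-edge.  Clamping (rather than
  zero padding) avoids manufacturing matching gradients at the field-of-view
  boundary; pixels with no real atlas support are the mixture model's job.
* **Sobolev operator.** `(id - a^2 Laplacian)^p` realized in the frequency
  domain with the periodic discrete-Laplacian symbol
  `(1 + a^2 sum_d 2(1 - cos(2 pi f_d h_d))/h_d^2)^p`; the multiplier is 1 at
  zero frequency and >= 1 everywhere.  Because the FFT is periodic, the
  velocity *update* is zeroed in a 2-voxel margin after smoothing, which
  keeps the velocity identically zero there and prevents wrap-around
  coupling of opposite edges.
* **Flow integration.** Forward Euler for `phi`, semi-Lagrangian updates
  for `phi_t^-1` and for the residual-transport maps; `nt = 5` timesteps by
  default (`nt = 3` in the desk-scale experiments).  Inverse-consistency
  error decreases empirically with `nt` and stays below half a voxel in the
  converged experiments; Jacobians of fitted flows stay positive.
* **Contrast solve.** Weighted normal equations.  Intensities are
  standardized (posterior-weighted zero mean / unit variance) before the
  Vandermonde basis is built — cubic bases on raw units are badly
  conditioned — and the coefficients are mapped back to raw units by
  binomial expansion, so reported `theta` always applies to raw
  intensities.  A relative ridge (`1e-6 * trace/cols`) keeps the solve
  well-posed on near-constant images; `ridge = 0` recovers the exact
  least-squares solution and is used where closed-form identities are
  asserted.
* **Step-size policy.** Gradients are rescaled so the first update per
  pyramid level has a configured physical size (default: 0.1 voxel of
  velocity, 0.4 voxel of translation, 0.02 on the linear part); accepted
  steps grow by 1.1x (capped at 20x), rejected steps halve all components.
  The velocity step is deliberately an order of magnitude below the affine
  steps so the linear transform stays near-optimal throughout.  Rigid and
  similarity families are maintained by projecting the linear part (SVD)
  after every step.
* **Initialization.** `v = 0`, affine = identity, `theta` = unweighted fit
  on the undeformed configuration, `mu_B` / `mu_A` = means of the 1%
  lowest- / highest-magnitude target pixels (backgrounds are typically
  empty, artifacts bright).  A coarse-to-fine block-average pyramid
  re-estimates posteriors at each level and upsamples the velocity.
* **Convergence.** Relative objective change below `tol` (1e-4 default)
  over a 10-iteration window, or the iteration cap.

### Verifying the velocity gradient

The analytic gradient is checked against central finite differences of the
discrete objective on a 16x16 problem.  The check probes *interior* voxels
at the optimizer's starting point `v = 0`: there the semi-Lagrangian
transport factors are exactly the identity and the symmetric difference of
the piecewise-linear interpolated objective coincides with the
central-difference image gradient the analytic formula uses, so agreement
to 1e-2 (observed: ~1e-6) is a sharp test of the formula rather than of
time-discretization error.  At nonzero velocity a pointwise check is not
attainable with linear interpolation — the interpolant's cell-wise slope
differs from the smoothed gradient at first order in the grid spacing — so
the transported-weight factors are additionally exercised by directional
derivatives along smooth perturbations at a documented looser tolerance,
and end-to-end by the recovery experiments.  Boundary voxels are excluded:
clamped sampling makes the objective non-smooth there, and the tapered
velocity margin pins them anyway.

## Slice-to-volume chain

A stack of 2D sections at strictly increasing section coordinates `z_i` is
registered to a 3D volume through a composed chain: per-slice 2D rigid
(slide placement, about the slice center), in-plane scale, shared 3D rigid,
shared diffeomorphism (optional).  Gradients of all rigid/scale components
follow the chain rule through the composition; the shared-diffeomorphism
gradient deposits per-pixel residual forces at their mapped volume
coordinates (nearest-voxel splatting) and smooths with `K`, which is
adequate because `K` low-passes the deposit.  Each slice keeps its own
separable-cubic contrast and its own posteriors.  Slices with fewer than 5%
matching-class pixels are excluded from the shared-parameter gradients for
that cycle so a fully failed section cannot drag the 3D pose.  Note the
shared 3D translation and the per-slice shifts split one gauge freedom;
recovery is therefore assessed on their composition.

Density quantification maps per-slice detector output through the chain
inverse into volume coordinates; voxels further than half the median slice
gap from any section are reported as missing (NaN), not zero.  Tables
report, per anatomical structure and per page plane (nearest-plane
binning), the tangle area (density sum times pixel area), the structure
area, and their ratio; 0/0 fractions are missing.

## Tangle-patch classifier

A small standard convnet classifies the center pixel of a 56x56x3 patch as
tangle / other tissue / background: three stages of (5x5 same-padded
convolution, ReLU, 2x2 stride-2 max pool) with 16/32/64 channels, a
1024-unit fully-connected layer with dropout 0.5, and a softmax
cross-entropy head — 3,280,675 trainable parameters, counted layer by layer
in `build_architecture`.  Pool geometry (2x2, stride 2) is implied by the
successive halving of the spatial dimensions.  Forward/backward passes are
written in numpy (shift-accumulate convolutions, float32) and train with
Adam (lr 1e-3, betas 0.9/0.999 — conventional defaults); training is
deterministic given the seed.  Whole-image densities come from a sliding
window over all valid patch centers (stride configurable; the 28-pixel
border has no valid centers and is reported as missing).

## Synthetic fixtures: what they do and do not show

All experiments run on generated data:

* **Phantom pair** (128x128 default): atlas levels background 0 / gray 1 /
  white 1.25; target levels 0 / 0.9 / 0.675 with a streak at 5; both images
  blurred with a Gaussian kernel of sd 2/3 px truncated to a 5x5 window and
  given additive white noise of sd 0.05; a wedge of target tissue is
  replaced by background; a smooth sinusoidal diffeomorphism (amplitude
  2.5 px) separates the geometries.  The brain-like geometry itself
  (ellipse, sulcal notch, concentric white matter) is an invention of this
  package and configurable.
* **Stain-swap pair**: same geometry rendered with gray/white intensity
  ranks swapped — separates cubic from affine contrast.
* **Hemisphere pair** (64x64 in the experiments): two contrasts of a
  labeled brain (gray/white/ventricle), mild warp, one hemisphere replaced
  by background.  Ten seeds, Dice scored on the retained half after mapping
  the atlas labels, with vs. without the constant classes.
* **Tangle patches**: dark central blobs on tissue texture vs. texture vs.
  near-white slide; default positive fraction 0.083.

These fixtures exercise the estimation machinery under known truth; they do
not emulate real stain color distributions, scanner shading, partial-volume
effects, or the full variability of histology damage.  Passing them shows
the algorithm recovers what its own generative model generates at realistic
noise — a necessary, not sufficient, condition for performance on real
sections.  The detector's perfect fixture accuracy likewise reflects
fixture separability, not expected real-data accuracy.

## Problem sizes

The shipped experiments use: 128x128 phantom, 20 EM cycles x 15 descent
iterations, single pyramid level; 96x96 textured self-recovery with 400
iterations at two levels (`sigma_R = 10` there — the truth warp is
noiseless and fairly strong, so the deformation penalty is kept weak);
64x64 hemispheres, ten seeds per arm; 16x16 gradient probes; patch-CNN
training on 150-240 patches for 8-10 epochs.  These sizes were chosen so
the whole suite runs comfortably on a single CPU while leaving each
experiment's conclusion unchanged at larger sizes.

## Known limitations

* Gradient transport is first-order accurate in `1/nt`; geodesic shooting
  and adjoint integration are out of scope, as are symmetric
  formulations — the model is asymmetric on purpose.
* Class noise levels `sigma_M, sigma_A, sigma_B` are user parameters, not
  estimated; they encode the physical noise model and need care.  Defaults
  set the constant classes 5x noisier than the matching class.
* Uniform class priors; no spatial smoothing of the label field.
* The E-step responsibilities assume spherical Gaussian noise per class.
* NIfTI volumes must have axis-aligned affines; oblique acquisitions are
  rejected rather than silently resampled.
* Per-slice rigid motions are not regularized toward their neighbors; a
  stack-coherence penalty would be a natural extension.
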