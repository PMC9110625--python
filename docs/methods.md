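# Methods

This note records the modelling choices, defaults and limitations behind
`poseface`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Head geometry and pose estimation

The head is a rigid ellipsoid with semi-axes (a, b, c), default
(0.7, 1.0, 0.8) model units — a slightly tall, slightly deep head shape.
These values are a configuration choice: nothing in the method constrains
them beyond a > 0, b > 0, c > 0, and all geometry is expressed in model
units so the absolute scale is arbitrary. Surface membership is tested
through the homogeneous quadric E₀ = diag(b²c², a²c², a²b², −a²b²c²) with
the tolerance scaled by |a²b²c²| so it is meaningful for any size.

Pose is an intrinsic yaw–pitch–roll rotation about the ellipsoid center
plus a translation. Axes follow image conventions (x = column rightward,
y = row downward, origin top-left, 0-based pixels): yaw rotates about the
vertical y axis (a head turn), pitch about x (a nod), roll about the
optical z axis. Angles are stored wrapped to (−π, π].

The camera is weak perspective — uniform scale s (pixels per model unit)
plus a principal-point shift — which is adequate when depth variation
across the face is small relative to the camera distance. Two consequences
are deliberate:

- depth translation tz does not affect the image, so `estimate_pose`
  optimizes only (yaw, pitch, roll, tx, ty) and carries tz through from the
  initial pose;
- at near-frontal poses yaw and tx are nearly collinear directions of the
  residual (both shift the projected points horizontally at first order),
  so yaw estimates under pixel noise are least certain at yaw ≈ 0 and
  sharpen as the pose turns away from frontal.

The optimizer is a small damped least-squares (Levenberg–Marquardt) loop:
central-difference Jacobian (step 1e-6), multiplicative damping adapted by
factors of 10, stop when the step norm falls below 1e-8 or after 100
iterations. Non-convergence is reported via a flag, never an exception.
Initialization is the previous frame's pose (identity for frame 0), which
matches the frame-to-frame tracking regime the method is designed for.

The 24 default anchors form clusters over the regions that deform most
under expressions — eyes (8), brows (2), cheeks (6), mouth (5), nose,
chin, forehead — placed as fractions of the semi-axes on the front
hemisphere.

## Tracking

Window flow uses the standard sum-of-products normal equations: the
structure tensor C_k = [[ΣIx², ΣIxIy], [ΣIxIy, ΣIy²]] and
D_k = (ΣIxIt, ΣIyIt)ᵀ over a (2w+1)² window, solved as (u,v) = −C_k⁻¹D_k.
The second component of D_k uses Iy (the x/y-symmetric form required for
the linear system to be the gradient of the windowed cost). Defaults:
w = 3; spatial gradients by central differences; subpixel windows by
bilinear interpolation; per-level Newton–Raphson iterations stop at an
increment below 0.01 px or 20 iterations.

The pyramid reduction smooths with the separable 1/4–1/8–1/16 kernel
(weights sum to 1, so constant images are invariant at every level) and
samples even coordinates; borders use reflect padding; level j has
⌈dims(j−1)/2⌉ pixels; j_max defaults to 3. Displacements propagate
coarse-to-fine, doubling per level, and compose as Σ_j 2ʲ d_kʲ.

A feature is lost when its window fails the texture test
(min eigenvalue of C_k < 1e-4 · window area), when its post-solve residual
(mean |It| after displacement) exceeds 0.05, or when it drifts out of the
frame with margin. Lost features hold no later positions and are never
re-detected — re-detection is out of scope.

## Gabor features

Kernels follow G(x,y) = (1/2πσ²) exp(−(x²+y²)/2σ²) exp[2πi u(x cosθ + y sinθ)]
on the integer grid [−n, n]². The five scale values {4, 4√2, 8, 8√2, 16}
are wavelengths λ in pixels with u = 1/λ; σ = λ/2 couples the envelope to
the wavelength, and the support n = ⌈2.5σ⌉ truncates the Gaussian at 2.5σ
(tail mass < 1%). Zero DC is realized by subtracting the mean of the real
taps (the imaginary part of an odd-phase kernel is already zero-mean), so
constant-illumination images produce responses below 1e-8.

Convolution is valid-region only. Because the kernel support varies with
scale (n = 5…20), all 40 magnitude maps are center-cropped to the smallest
valid region before the ρ-strided subsample (ρ = 4 default), which keeps
the descriptor dimension fixed at 40 × ⌈H′/ρ⌉ × ⌈W′/ρ⌉. The magnitude
vector is z-score normalized per descriptor; the two-bit phase code
(x₁, x₂) = ([G₁ ≥ 0], [G₂ ≥ 0]) is exposed but the classifier consumes
magnitudes.

Patches are extracted per tracked anchor, default 48×48: the largest
default kernel spans 41×41 pixels, so the patch must be at least that
size for a valid convolution; 48 leaves an 8×8 valid grid. Lost anchors
contribute zero blocks so descriptors keep a fixed dimension.

## Ada-AdaSVM

Weak learners are soft-margin RBF-SVMs with kernel
exp(−‖x−x′‖²/2δ²) — sklearn's `gamma = 1/(2δ²)` — and regularization
C = 1.0; standalone weak training defaults to δ = 0.1, the typical best
operating point of a tuned weak SVM. Sample weights enter as libsvm
per-sample weights scaled to mean 1.

The boosting loop initializes weights at 1/(2a) (positives) and 1/(2b)
(negatives) — the class-balanced normalization with Σw = 1 — and anneals
δ from δ_ini = 10 by division with δ_step = 2 down to δ_min = 0.01
whenever a round's weighted error ξ_t reaches 1/2 (trigger at ξ_t ≥ 1/2).
The default on chance failure retries the round with the current sample
weights; a full weight restart is available via config but discards the
boosting state accumulated so far. ξ_t is clipped to [1e-10, 0.5 − 1e-10]
before α_t = ½ ln(1/ξ_t − 1). Two termination refinements:

- a round with ξ_t ≈ 0 retains its (clipped, large-α) classifier and stops
  the loop: the weight update would be a uniform rescale, so every further
  round would re-train the identical learner;
- if δ reaches the floor with no learner beating chance the ensemble is
  returned partial with a warning flag, and an ensemble with zero retained
  rounds votes margin 0 everywhere (prediction falls to the ≥ 0 sign
  convention) rather than raising.

Feature selection runs the same loop with each round restricted to the
single feature minimizing the weighted error; the first K distinct indices
are returned in selection order, topped up by initial-weight error ranking
if boosting converges on fewer than K distinct features. The per-feature
weak learner is a 1-D RBF-SVM by default; a vectorized decision stump is
available (`weak="stump"`) and is roughly an order of magnitude faster at
equal selection quality on the synthetic fixtures.

LOSOCV holds out all samples of one subject per fold. The reported error
is the misclassification rate, identical to (1/2n) Σ|f(xᵢ) − yᵢ| for ±1
labels since each mistake contributes 2. Multiclass problems use
one-vs-rest ensembles with maximal-margin prediction, ties to the lowest
class index.

In the end-to-end pipeline, stump-mode selection of K = 64 features runs
inside every CV fold before the one-vs-rest ensembles. This both mirrors
the select-then-classify architecture and keeps the annealing schedule
matched to the data: raw patch descriptors are ~10³–10⁴-dimensional, where
pairwise distances of z-scored features are far larger than δ_ini = 10 and
an RBF weak learner would start in its memorization regime; after
selection, distances are O(√K) and the schedule anneals through the
informative range.

## Synthetic data

The renderer back-casts each pixel through the weak-perspective camera
onto the posed ellipsoid (front root of the per-pixel quadratic) and
shades it with a procedural texture attached to the model frame, so
surface points keep their appearance under rotation and optical flow has
stable gradients. No lighting model is applied; background is constant
0.5.

The texture is band-limited value noise — 14 random 3D cosine gratings
with frequencies in 9–16 cycles/model-unit plus 10 smooth blobs
(σ = 0.12 units) — at contrast 0.35 around mid-gray. Pure per-pixel noise
is avoided because it aliases under rotation. Each subject gets its own
pattern seed (identity variation); each expression class adds a localized
deformation: a directional cosine carrier windowed by Gaussians
(σ = 0.18 units) at a class-specific anchor group (mouth, eyes, cheeks,
brows, …), at amplitude 0.6 by default. Carrier frequencies are spaced
geometrically (3 · 1.5ᶜ cycles/unit — wavelengths ≈ 16, 10.7, 7.1 px at
the default camera scale), all below the subject-identity band, so
expression signatures and subject identity are spectrally separable and
the class signal lands inside the Gabor bank's sensitive range. Anchor
visibility is flagged from the outward-normal sign; at profile yaw the
far-side anchors go invisible, qualitatively reproducing the difficulty
of extreme poses.

The default benchmark renders 3 classes × 5 subjects × 2 repetitions of
5-frame 128×128 sequences swept over ±15° yaw — 30 sequences, a size
chosen so the full pipeline (render, track, extract, select, classify,
5-fold LOSOCV) completes in about a minute on one core while leaving
each LOSOCV fold 24 training sequences. With the deformation amplitude at
0 the labels carry no signal and LOSOCV accuracy sits at chance (exactly
1/3 when every ensemble returns empty and the tie-break picks a constant
class).

What passing on this fixture does not show: robustness to photometric
variation (lighting, shadows, sensor noise), non-rigid facial motion
beyond texture deformation, occlusion, identity-dependent face shape, or
real-image statistics. The fixture isolates the geometric and spectral
mechanics of the method; absolute accuracies on it say nothing about
accuracy on real face databases.

## Numerical choices and degenerate inputs

- Pose estimation requires ≥ 3 non-collinear correspondences; fewer, or a
  collinear triple, raise an insufficient-data error.
- The flow solver treats a window with min-eigenvalue below threshold as
  lost rather than ill-conditioned-solvable.
- `alpha` is total on [0, 1] via clipping; schedule validation enforces
  δ_ini > δ_min > 0 and δ_step > 1.
- Feature z-scoring guards the zero-variance case (all-zero descriptor
  stays zero).
- All randomness flows through explicit integer seeds (default 42);
  identical config + seed reproduces frames, descriptors, ensembles and
  predictions bit-exactly.

## Known limitations

- Weak perspective makes tz unobservable and weakens yaw/tx identifiability
  near frontal poses (see above).
- The tracker has no affine or illumination-compensated window model, so
  strong in-plane rotation or scale change within a window degrades flow.
- Ada-AdaSVM's annealing only shrinks δ; a problem needing a larger-than-
  initial kernel scale must set δ_ini accordingly.
- The CLI's 10-fold mode assigns folds randomly without subject grouping,
  as a deliberate contrast to LOSOCV, and will leak identity when samples
  per subject are correlated.
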