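# Methods

This note documents the models and numerical choices behind `neotemplate`:
what each stage assumes, which parameters matter, what the synthetic
phantoms do and do not emulate, and where the design was genuinely open.

## Coordinate and transform conventions

World coordinates are RAS in millimetres; voxel indices are 0-based with
voxel centres at `origin + direction · diag(spacing) · index`. All spatial
transforms use the *pull* (resampling) convention: a transform maps a point
of the output/fixed space to the corresponding point of the input/moving
space, and warping an image means sampling it at the mapped points. A
composite transform lists its components in the order they act on the
moving image; under the pull convention the point map evaluates the list
back-to-front. Diffeomorphic transforms store paired forward/inverse
displacement fields (mm, world axes) on an explicit fixed grid; the inverse
is computed by fixed-point iteration `g(x) = −f(x + g(x))` (30 iterations),
which for the smooth fields this pipeline produces reaches far below 0.1
voxel mean residual. Jacobian determinants are computed by central finite
differences of the displacement field in world units.

## CT preprocessing

**Otsu threshold.** Implemented as an exact exhaustive maximization of the
between-class variance over every midpoint between consecutive distinct
intensities, with ties resolved to the smallest threshold. This makes the
operator reproducible and directly checkable against a brute-force oracle;
on images whose histogram has an empty gap between modes, any threshold in
the gap ties, and the smallest-threshold rule picks the gap's lower edge
midpoint.

**Head mask.** Values below −1024 HU are non-physical (the −3000
reconstruction rim) and are clamped to −1000 before thresholding; otherwise,
on coarse grids where the one-voxel rim carries appreciable mass, Otsu
happily separates *rim from everything else* instead of air from head. After
thresholding: binary opening (1-voxel ball) to detach thin bridges, largest
connected component (drops pillow/pacifier blobs), closing (2-voxel ball),
hole filling. Sizes are exposed as parameters; the defaults were chosen once
for the phantom geometry and are deliberately small so the mask stays within
one voxel of the true head boundary.

**Background cleaning** sets every voxel outside the head mask to exactly
−1000 HU. It is idempotent and eliminates the rim as a side effect of the
rim lying outside the head.

**Intensity transform.** Piecewise linear through the anchor points
(−1000→0), (−100→900), (−99→901), (100→3100), and `v→v+3000` above 100 HU.
The first segment's interior is taken linear (slope exactly 1) — the
simplest map consistent with the printed endpoints — and the short
(−100,−99)→(900,901) connector keeps the map continuous and strictly
increasing, hence invertible; the inverse is the same interpolation read
backwards and round-trips to 1e−9. Inputs below −1000 are clamped (and
logged) since preprocessing removes them anyway; the transform is
implemented as a continuous map, not an integer lookup table, because only
the continuous version satisfies all five anchors simultaneously.

## Coupled level-set intracranial extraction

Two signed-distance functions (negative inside; reinitialized by Euclidean
distance transform every 10 iterations) evolve under geodesic-active-contour
dynamics: an interior surface initialized as the head eroded by
`inner_erosion_mm` (default 15 mm — beyond scalp + skull, so it starts
inside the cranial cavity) grows outward; an exterior surface initialized at
the head boundary shrinks inward. The speed of each front is
`balloon · g(x) · gate`, with a curvature term (weight 0.3) and an upwinded
edge-attraction term `η ∇g·∇φ` (η = 2, velocity components clipped to ±0.5
to protect the CFL step).

The stopping map `g` is the product of the standard edge factor
`1/(1+|∇(G_σ*I)|²/λ²)` (σ = 2 mm, λ = 50 HU/mm) and a *region* factor — a
soft step that vanishes where the smoothed intensity exceeds the bone range
(threshold 300 HU, width 100 HU). The edge factor alone stops a front at a
bone *edge* but lets it tunnel through the bone *plateau* between the two
edges; the region factor closes that hole. This is the natural
active-region form for CT, where bone is identified by absolute intensity.

Coupling: each front's propagation is multiplied by a soft gate that
vanishes as the distance to the other surface (read off the other φ) falls
below one voxel, so at fontanels — where no bone stops them — the two
fronts meet and stall. Non-crossing (`interior ⊆ exterior`, i.e.
`φ_in ≥ φ_out`) is additionally enforced by an exact clamp after every
step, so the invariant holds at every iteration by construction, not just
at convergence. The `touched` map marks front voxels whose inter-surface
distance is at the gate threshold; on phantoms it localizes to the fontanel
sectors within ~2 voxels.

Convergence: the evolution stops when the mean |Δφ| on the one-voxel front
band falls below 1e−3 mm, or — the criterion that fires in practice — when
no voxel changes region membership for 12 consecutive iterations. Both
checks are suppressed for the first 20 iterations because the fronts start
a full voxel away from any zero crossing and sub-voxel motion would
otherwise look like convergence. The intracranial mask is the hole-filled
largest component of the interior region, intersected with the head mask;
an optional pair of add/remove masks stands in for expert manual revision.

## Registration

Both registrars are implemented in-package; an external toolkit appears
only as an independent oracle in one cross-check test.

**Affine (12 parameters).** Translation, Euler rotations, log-scales and
shears, centred on the fixed-image centroid, optimized with Powell's method
(derivative-free; the MI objective is piecewise smooth at best) over a
multiresolution pyramid (downsampling ×4/×2/×1 with Gaussian smoothing
2/1/0 voxels, 100/70/40 iterations). Metrics: mutual information on a
32-bin joint histogram, or global Pearson correlation. Sampling is the full
fixed grid — no stochastic subsampling — so results are deterministic. The
final transform is evaluated against the initial one at full resolution and
the initializer is returned if optimization failed to improve, which makes
the metric-monotonicity contract unconditional. A centre-of-mass +
principal-axes rigid initializer replaces any manual pre-alignment; its
eigenvector sign ambiguity is resolved toward the fixed image's axes and
the result projected onto the nearest proper rotation.

**Symmetric diffeomorphic.** Greedy compositive demons per direction:
symmetric intensity forces `(F−J_w)(∇F+∇J_w)/2` normalized demons-style,
update capped at 0.6 voxel/iteration, fluid-like smoothing of the update
(σ = 1 voxel) and elastic-like smoothing of the composed total field
(σ = 1 voxel), over the same 3-level pyramid. A divergence guard tracks the
similarity each iteration and reverts to the best state after 5 consecutive
degradations. Symmetry is obtained structurally: the algorithm runs in both
directions and returns `½(u_fwd + inv(u_bwd))`, so exchanging the two
images yields exactly the mirrored construction; the returned inverse field
is then recomputed by fixed-point inversion so forward∘inverse is identity
to sub-voxel tolerance regardless of the averaging. For multimodal pairs
(MI metric) the moving image is remapped through the joint-histogram
conditional mean `E[fixed | moving-bin]` — re-estimated from the currently
aligned pair every 5 iterations — so the monomodal force model applies; the
divergence guard then tracks correlation of the remapped pair.

The diffeomorphic step assumes affine pre-alignment (it is always preceded
by the affine registrar in the pipeline); it recovers the residual smooth
deformation, not gross pose. Homogeneous image cores are an intrinsic
aperture problem: displacement there is reconstructed only by smoothness
propagation from boundaries, which is why the landmark-recovery guarantee
is stated for the affine+diffeomorphic chain.

## Groupwise template

Per iteration: register every subject to the current template (affine +
diffeomorphic, correlation metric for this intra-modality step), average
the warped subjects voxelwise (appearance update), then warp the average by
`−0.25 ×` the mean forward field, Gaussian-smoothed at σ = 1 voxel (shape
update — a small diffeomorphism toward the population mean shape). The
damping keeps every shape step well inside the diffeomorphic regime; the
full average would overshoot because the per-subject fields are themselves
greedy estimates. Initializing with the MR-space reference anchors the
template in that space, which is the point of the bimodal construction.
Because that initial template carries MR appearance, the *first*
iteration's subject-to-template registrations are inter-modality; the
pipeline therefore drives template building with the configured
inter-modality metric (MI by default), while correlation remains the right
choice — and the tested one — for cohorts whose initial template is
already CT-valued. Two iterations are the default; the per-subject
similarity statistics are insensitive to running four, which the
acceptance suite checks. The
appearance update is the plain mean (a trimmed mean would guard against
registration failures, but with the abort-on-failure contract a failed
subject never reaches the average).

## Mutual information and evaluation

MI is computed from a joint histogram (64 bins for evaluation, 32 inside
registration) with `0·log 0 := 0`, in **bits** (base-2 logs) by default and
switchable to nats; the clinical literature rarely states the base, and the
choice rescales but never reorders comparisons. Evaluation MI is computed
over the whole volume (an optional mask argument exists) against the
template smoothed with a 2 mm FWHM Gaussian (σ = FWHM/(2√(2 ln 2)),
replicate-edge boundary). Test-image normalization for evaluation uses
correlation for both the affine and diffeomorphic steps, matching the
intra-modality character of CT-to-CT-template alignment even though the
construction pipeline's inter-modality steps use MI.

## Synthetic phantoms

A phantom is a nest of ellipsoids — scalp (5 mm), bone shell (5 mm), CSF
rim (4 mm), cortical grey matter (6 mm), white-matter core — with fontanel
gaps cut through the bone shell as angular sectors (defaults: a wide
anterior-superior sector of 35° and a posterior one of 25°). CT tissue
means follow the HU convention (air −1000, CSF 15, WM 25, GM 41, scalp 30,
bone 1000) with additive Gaussian noise (σ = 8 HU); the MR channel inverts
the contrast (bone 60, WM 520 on a 0–1023 scale) with doubled noise, which
reproduces the CT/MR contrast inversion that makes the registration
multimodal. Nuisance structures: soft-tissue blobs placed outside the head
(pillow/pacifier) and a one-voxel ellipsoidal rim at exactly −3000 HU near
the field-of-view boundary. The skull is thicker than a real neonatal
calvarium because it must span ≥2 voxels at the 2–3 mm test spacings;
geometry is parametric, so finer studies can thin it.

Populations perturb a known mean anatomy by a random rigid motion (defaults
σ = 3 mm, 5°) plus a Gaussian-smoothed random vector field (smoothness
12 mm, mean magnitude 3 mm), applied to the *label map* (nearest
neighbour), from which fresh CT/MR images with subject-specific noise are
synthesized — so every subject's masks are exact and its generating
transform is carried as ground truth. Fields are verified to have positive
Jacobian determinant everywhere; a folded draw is damped by 0.7 and
redrawn.

What the phantoms do **not** emulate: cortical folding, skull curvature
variation and real suture geometry, CT beam hardening and metal artifacts,
MR bias fields, and partial-volume mixtures beyond linear interpolation.
Passing tests therefore demonstrate correctness of the algorithms under
controlled conditions — recovery of known transforms, closure of known
gaps, unbiasedness against a known mean — not clinical-grade accuracy on
real neonatal data.

## Problem sizes and determinism

Default test problems use 40³–64³ grids at 1.25–3 mm spacing, registration
pyramids truncated at the ×2 level, and a 5–8-subject population for the
groupwise studies; these sizes were chosen so the entire suite runs in
minutes on one CPU while every contract is still exercised at sub-voxel
tolerances. All randomness flows through explicit seeds (phantoms only;
the optimizers are deterministic by construction), so identical inputs and
configuration reproduce outputs bit-for-bit.

## Known limitations

* Thin-shell intensities are resolution-limited: a skull spanning only ~2
  voxels loses roughly a third of its peak HU to trilinear partial volume
  across the pipeline's resamplings, so bone-threshold overlap statistics
  of the final template are only meaningful on grids that resolve the
  shell with ≥4 voxels (clinical 0.47 mm data resolves it with 6–10).
* The level-set parameters (λ, bone threshold, gate width) are tuned for
  calibrated HU images; running the segmentation on intensity-transformed
  data would need rescaled defaults.
* The demons-style registrar regularizes in displacement space; very large
  deformations (beyond the ~6 mm the tests exercise) should be handled by
  the affine stage or a coarser pyramid level first.
* Pipeline stages write and reload every intermediate artifact, but reruns
  recompute all stages; no content-hash caching is implemented.
* The MR intracranial template builder assumes its inputs are already
  aligned to a common space, as is the case for the reference MR cohort it
  models.
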