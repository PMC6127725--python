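# Methods

## Problem setting

Developing myotubes probe their surroundings with filopodia: actin-rich
protrusions roughly 0.1–0.3 µm thick and a few µm long, radiating from a
bright cell body.  The acquisitions this package targets are shallow
confocal time series — 5–7 z-sections at 0.7 µm spacing, one stack every
15 s for ~15 min — with sub-0.2 µm pixels.  Two properties dominate the
design: extreme z-anisotropy (a z step costs 4–7 pixels' worth of
distance) and objects only 1–2 pixels wide sitting next to a structure
(the cell body) several hundred times their area.

## Detection

Each time point's z-stack is processed independently.

**Binarization.** The frame is quantized into three intensity labels by
k-means over all voxels of the stack, with no connectivity constraint, and
every voxel outside the lowest-mean label is foreground.  This is
connectivity-free superpixel labeling taken to its zero-compactness limit;
it behaves as a two-threshold quantization into background / cell body /
bright protrusions.  Two implementation points matter.  First, cluster
centers are seeded evenly over the intensity *range*, not at quantiles:
with ~99% of voxels in the background mode, quantile seeds all land inside
it and Lloyd's iterations converge to a split of the background rather
than a separation of background from structure.  Second, the clustering
pools the whole z-stack rather than running per plane: a boundary plane
containing only noise has no three-level structure of its own, and
clustering it in isolation assigns arbitrary noise tertiles to foreground.
A spatially regularized variant (scikit-image SLIC with the reference
compactness 10 on a [0, 255]-rescaled plane) is kept behind
`SegmentationConfig.spatial_slic`; with only three labels its grid-seeded
centers all start at background intensity and the partition can collapse
to spatial blocks, so it is not the default.

**Cell-body mask.** Per z-plane: Gaussian blur (σ = 5 px), adaptive
threshold against a Gaussian-weighted local mean (999×999 neighborhood,
clamped to the largest odd size that fits the image), then a binary
opening (disk radius 14) and an erosion (disk radius 5).  The opening is
the step that actually separates body from protrusions on a quiet
background: the Gaussian-weighted local mean scales with a blurred ridge
itself, so a σ=5-blurred filopodium stays above threshold at *any*
contrast and leaves a ~20 px ribbon that the 5 px erosion alone cannot
remove.  The opening radius must exceed half the width of a blurred
protrusion ridge (~2σ + tube radius ≈ 12 px) and stay below the body
half-width; 14 px satisfies both for bodies ≳ 3 µm across.  Setting
`body_opening_radius = 0` restores the plain blur + threshold + erode
recipe.

**Vesselness.** The Hessian of the *binarized* frame is computed with
Gaussian derivatives at scales {1.0, 1.5, 2.0} voxels (filopodia are 1–2
voxels wide), γ-normalized (×scale²), with z-derivatives corrected for
voxel anisotropy (spacing `(dz/dx, dy/dx, 1)`; disable via
`anisotropy_correction`).  Eigenvalues are ordered |λ₁| ≤ |λ₂| ≤ |λ₃| and
combined as

    V = (1 − exp(−r_a²/2α²)) · exp(−r_b²/2β²) · (1 − exp(−s²/2c²)),

with r_a = |λ₂|/|λ₃| (plate suppression), r_b = |λ₁|/√|λ₂λ₃| (blob
suppression), s the Frobenius norm (contrast), and V = 0 wherever λ₂ > 0
or λ₃ > 0 (bright-tube convention — GFP-labeled filopodia are bright on
dark).  Defaults α = β = 0.5 and c = half the frame's maximum s at each
scale follow the standard recommendation for this filter family; the
response is the maximum over scales.  All three weights and the scale list
are configurable, since the weighting is known to be data-dependent.

**Cleanup.** The vesselness field is binarized by the same 3-label
clustering, followed by a binary closing with a cube (Chebyshev-ball)
footprint of radius 1.  The cube is deliberate: closing with a Euclidean
ball can *never* bridge a gap in a one-voxel-wide line (the lateral
extreme of the ball always escapes the dilation), whereas a cube of radius
r heals gaps up to 2r and is consistent with the package's 26-connectivity
convention.  Connected regions (26-connectivity, full 3D stack) under 200
voxels are then removed — the threshold is high because a filopodium's
vesselness patch spans several z-slices.

**Skeleton and segments.** The mask is thinned by 3D medial-axis
skeletonization (Lee's algorithm, via scikit-image), skeleton voxels
inside the cell-body mask are removed, and endpoints are regrown along the
vesselness mask (`extend_skeleton_tips`, capped at 8 voxels, never into
the body): thinning retracts a filament's ends by roughly its radius, a
bias that matters at the 3 µm inclusion boundary.  Each connected skeleton
component is decomposed into simple paths at branch voxels (≥ 3 neighbors
in 26-connectivity); traversal order is lexicographic, so the decomposition
is deterministic.

## Curation contract

Manual editing is encoded as an ordered JSON script of commands:
`remove(segment_ids)`, `accept(segment_id → instance_id)`,
`merge([segment_ids] → instance_id)`.  Segments not referenced by any
command are kept as singleton instances, so a script need only name what
it changes; `auto_accept` emits the explicit identity script for
unattended runs.  Merging chains segments by repeatedly joining the
nearest endpoints (error if they are further than `merge_gap` = 5 voxels
apart, naming the offending ids).  Each surviving instance is oriented
base→tip, the base being the endpoint nearer the cell-body mask (or, with
no body in the frame, nearer the centroid of all detected voxels — an
arbitrary but deterministic anchor).

## Length estimation

`path_length_vox` is the raw index-space polyline length.  The physical
length `path_length_um` is measured on a 5-point moving average of the
voxel path with the endpoints pinned: a voxel path is a staircase, and on
these stacks a single spurious one-slice z-flicker charges a full 0.7 µm
against a 0.1 µm pixel — raw summation inflated a 3.3 µm filopodium to
7.8 µm in testing, while the smoothed estimator reads true centerlines to
about ±0.25 µm (validated against the generator's analytic lengths).
Endpoint pinning keeps the measured curve spanning the full base→tip
extent; without it the window average pulls both ends inward by ~0.1 µm
each.

## Linking

For each frame t, the candidate set pairs every current filopodium with
every track whose most recent instance lies within the preceding five
frames and whose minimum pairwise voxel distance is ≤ 25 pixels (raw index
units, z unscaled, because the cutoff is stated in pixels; a calibrated
mode exists).  Each candidate is scored S = 0.46·M_L + 0.6·M_D with
M_L = |L_c − L_p|/max{L_c, L_p} on the physical path lengths and
M_D = (1 − cos θ)/2 on the average non-normalized direction vectors (their
magnitudes cancel under the cosine; 0 = parallel, 1 = antiparallel; a
zero vector scores an uninformative 0.5 with a warning).  Candidates are
processed in ascending score with ties broken by (M_L, instance id, track
id); a pair links only if neither side is already linked in this frame;
unmatched filopodia start new tracks.  The weights are used exactly as
given, not renormalized.  Candidate generation uses each track's most
recent instance in the window (mode `"any"` considers every instance and
keeps the best-scoring pairing).  A vectorized centroid + radius bound
prefilters pairs before exact distance computation; the bound is exact
(min path distance ≥ centroid distance − both radii), so the candidate set
is unchanged while dense noise scenes stay tractable.

## Quantification

Tracks are kept iff maximum length ≥ 3 µm *and* lifetime ≥ 2 frames (both
closed bounds; lifetime counts frames present, with gaps allowed — a
strict-consecutive variant is a flag).  Reported quantities: per-frame
filopodium counts over a window (default 15 min; both the mean per-frame
count and the distinct-track count are emitted, since "number of filopodia
in a window" admits both readings), the ECDF of per-track maximum lengths,
and a shifted-exponential fit of maximum lengths above the 3 µm cut-off —
maximum-likelihood rate 1/mean-excess, with the Kolmogorov–Smirnov
distance against the fitted law as a (optimistically biased, since the
rate is estimated from the same data) goodness-of-fit diagnostic.  The
exponential shape is the expected signature of stochastic length
generation: many short filopodia, gradually fewer long ones.  Group
comparisons use the two-sided Mann–Whitney U test, exact for group sizes
≤ 20 and the tie-corrected normal approximation otherwise.

## Synthetic movies

The generator renders the study conditions end to end: a static ellipsoid
body (radii ~0.13 × 3 × 3 µm³-scale, intensity 140) imaged through an
axial Gaussian PSF (σ = 0.5 µm) so out-of-focus body light reaches every
slice, plus filopodia as Gaussian-profile tubes (lateral σ = 1.5 voxels)
around analytic centerlines anchored on the body surface.  Default scene:
60 frames × 6 slices × 256² pixels at dx = dy = 0.1 µm, dz = 0.7 µm,
dt = 15 s, 8 filopodia.  Maximum lengths are drawn from
offset + Exp(rate): offset 3 µm, rate 0.5 µm⁻¹, capped at 10 µm so tips
stay in the field; per-frame lengths follow a triangular grow–retract
profile between the 3 µm visibility floor and the drawn maximum, and tips
wave laterally (bounded bend + per-frame jitter ≤ `drift_px_per_frame`).
Noise is Poisson shot noise on the photon counts plus Gaussian read noise
(σ = 3), giving peak SNR ≈ 10 at tube intensity 200 over background 10 —
the physical confocal noise model, in which the dark background is quiet
and the signal carries the noise.  Everything derives from one seeded
generator, so a fixed seed reproduces the movie bit for bit.

What the generator does **not** emulate: lateral PSF blur beyond the tube
profile, photobleaching, neighboring cells and tissue clutter, filopodium
branching by default (a branched mode exists to exercise the segment
splitter), and bases that migrate along the body surface.  Passing the
recovery tests therefore demonstrates correctness of the algorithmic chain
under realistic geometry and noise, not robustness to every property of
embryo recordings — the curation step exists precisely because real fields
contain structures the detector cannot classify.

Ground truth records, per frame and filopodium, the rasterized centerline,
the analytic length, and the mean direction.  `score_against_truth`
matches detections to true centerlines per frame (greedy on mean
point-to-centerline distance, one-to-one, within 5 voxels), and reports
recall, precision, identity accuracy (the fraction of consecutive
frame-pairs within a track whose matched true identity agrees; pairs with
an unmatched end count as wrong), per-detection length bias/RMSE, and the
RMSE of per-filopodium lifetime maximum lengths.

## Numerical and design notes

- All 3D component operations use 26-connectivity (thin diagonal filaments
  fragment under 6-connectivity).
- Hessian eigenvalues come from `numpy.linalg.eigvalsh` on the assembled
  3×3 fields; "flat" regions carry a ~1e-4 kernel-truncation residue.
- Determinism: k-means seeding, lexicographic traversal and explicit
  tie-break rules make detection, splitting and linking reproducible;
  the only randomness anywhere is the simulator's seeded generator.
- Degenerate inputs: constant frames binarize to all-background with a
  warning; zero direction vectors score M_D = 0.5; a quantification window
  longer than the movie is clamped with a warning.
- Problem sizes in the validation suite: the end-to-end check runs the
  default 60-frame 256² scene once; property tests use 2-filopodium 128²
  scenes with 2–10 frames.  These sizes exercise every code path while
  keeping the suite in the minutes range.
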