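# Methods

This note records the models, numerical choices, and deliberate design
decisions behind `spinefuse`, in the spirit of a package methods appendix.

## The measurement problem

Bone-marrow edema in the spine appears hyperintense on fat-suppressed
(STIR) MRI. Judging its change between two scans requires (a) knowing
where each vertebral unit (VU) is, (b) bringing the two scans into spatial
correspondence without bending the bone, and (c) comparing intensities.
The package decomposes the problem exactly along those lines:
atlas-based segmentation → global non-rigid alignment → per-VU rigid
restriction → color-encoded comparison → ordinal scoring and agreement
statistics.

## Coordinate conventions

Everything geometric is expressed in world millimeters through the NIfTI
affine. The phantom writes a scaled-permutation affine (array axes map to
anterior-posterior, inferior-superior, and left-right world axes
respectively), so any code relying on array-index order rather than the
affine fails immediately in tests. The superior-inferior direction used
for anatomical ordering is the world z axis, read through the affine, not
an array axis. Rationale: sagittal spine voxels are strongly anisotropic
(≈1.25 × 1.25 × 4.4 mm), so "rigid in index space" is not rigid in the
scanner frame.

## Segmentation

* **Label propagation** samples each atlas mask at the target voxel's
  mapped position with nearest-neighbor interpolation (labels must not be
  averaged); positions outside the atlas extent become background.
* **Majority vote** counts background as a candidate. Ties break toward
  the smallest label value. This is a pure determinism device: with 11
  atlases ties are rare but possible, and a documented tie-break makes
  reruns bit-identical.
* **Component labeling** uses 26-connectivity in 3D; components under 20
  voxels are discarded as noise. Survivors are ordered by centroid along
  the superior-inferior axis (descending for top-down labeling from C2,
  ascending for bottom-up labeling from S1, the latter matching
  lower-spine acquisitions). Exact centroid ties fall back to the
  anterior-posterior then left-right centroid, with a warning. A count
  that differs from the expected 24 raises `SegmentationFailure` carrying
  the observed count — segmentation failure is an expected clinical event,
  not a crash, and the CLI maps it to its own exit code. A
  manual-correction hook merges a correction mask over the automatic one
  and logs the provenance of every overridden voxel.
* **Vertebral units.** The "mid-point" of a body is its voxel-centroid
  coordinate along the superior-inferior axis. Alternatives (bounding-box
  middle) are less robust to tilted bodies. VU *k* = voxels of body *k* at
  or below its mid-point plus voxels of body *k*+1 strictly above its
  mid-point; within each interior body the two half-masks partition the
  body exactly (tested). 24 bodies give 23 VUs; VU1 = C2/C3, VU23 = L5/S1.
* The atlas outlines deliberately **under-segment** the bone (default
  erosion margin 1.3 mm, about one in-plane voxel): for locally rigid
  alignment, a region that stays inside the cortex is preferable to one
  spilling into non-rigid soft tissue. Per-body Dice of ~0.85–0.9 against
  the full ground-truth bodies is therefore the intended operating point,
  not a deficiency.

## Locally rigid alignment

* The global registration is a **pluggable contract** returning a dense
  displacement field on the TP1 grid (mm, world frame). Backends:
  `synthetic` (an analytic field — the phantom's exact truth), `precomputed`
  (vector NIfTI from any external registration tool), and `demons`
  (SimpleITK displacement-field registration, exploratory). The package
  does not implement non-rigid registration itself; its contribution
  starts where the field ends.
* **Landmark transform.** Landmarks are *all* VU voxels, uniformly
  weighted (a subsampling stride exists but defaults to off — exactness
  first; intensity weighting is a noted alternative that the reference
  workflow does not use). The rigid fit is the closed-form Kabsch/Umeyama
  solution: SVD of the centered cross-covariance, with the smallest
  singular direction flipped if the optimal orthogonal matrix would be a
  reflection, then a re-orthonormalization pass so the returned rotation
  satisfies RᵀR = I to 1e−10. Collinear or <3-voxel landmark sets raise a
  degenerate-geometry error. `rms_residual_mm` reports the post-fit RMS
  landmark error — a useful per-VU quality indicator (it grows with the
  non-rigidity of the field across the VU).
* **Direction symmetry.** The method can be run TP1→TP2 or TP2→TP1, so
  segmenting one time point suffices. When the within-VU field is a
  single rigid motion, the two directions are exact mutual inverses
  (verified to ~1e−6°). With genuinely per-body motion the VU field is a
  mixture of two rigids and the two directions agree only approximately;
  the `align_reverse_equivalence_check` report quantifies the discrepancy
  per VU.
* **Resampling** uses linear interpolation for intensities and
  nearest-neighbor for labels. The rigid transform is applied within the
  VU's region of interest dilated by a default 5 mm margin (a display
  parameter: the fused image should show some context around the bone).
  Out-of-extent samples receive a fill value and are excluded from the
  validity mask.

## Color-encoded fusion

rgb = round(clip(I₁·(255,128,0) + I₂·(0,127,255))), rounding half-up after
clipping, for bit-exact reproducibility. Consequences asserted as
invariants: equal inputs give channel spread ≤ 1 (gray); blue−red is
monotone in I₂; each input is recoverable from its pure channel to within
1/255. Normalization uses one **shared scalar window** (default: max over
both volumes; a fixed window is available for sensitivity analysis) — per
spectrum of possible readings of "no intensity standardization", a shared
scalar is the most conservative choice that still maps raw intensities
into color space, and it cannot introduce a global color cast when one
scan is uniformly brighter. No per-image histogram operation is ever
applied. Whether the original interactive tool applied a display window
before fusion is unknowable from the outside; the shared-scalar default is
a documented choice, and `window=` makes it explicit at every call.

## Scoring and agreement

* Change scores live on −2…+2 (0 = no net change, with a flag for
  "inflammation present but unchanged"); Berlin status scores on 0…3 per
  time point, change = status(TP2) − status(TP1) on −3…+3 after
  de-blinding the time order. Sheets are CSV-interchangeable and allow
  missing VUs (real cohorts have exclusions); statistics receive explicit
  missingness.
* The machine surrogate for the reader, `quantify_vu_change`, is the mean
  normalized intensity difference over VU voxels with valid resampling.
  The end-to-end pipeline restricts it to the **bone interior** (voxels
  farther than ~1.1 in-plane voxels from the bone/background boundary):
  at the cortex edge, the residual misalignment left by the rigid
  compromise would otherwise contribute a systematic negative bias that
  can swamp a small lesion signal. This mirrors what a human reader does —
  judge the marrow, not the edge.
* The inter-method comparison is on signs only: d = sign(mean CA change of
  two readers) − sign(mean Berlin change of two readers). The strict sign
  is used, so opposing reader scores (+1/−1) yield a mean of 0 and sign 0.
  |d| ≤ 1 means the methods never assert opposite directions. The
  direction convention (CA − Berlin) is configurable via a flag because
  the two plausible orderings are both defensible; the default is
  documented and the flip is a single argument.
* **ICC(A,1)** is computed from the two-way ANOVA mean squares, with the
  McGraw–Wong F-based 95% interval (Satterthwaite degrees of freedom) —
  the definition mainstream statistical packages label "two-way,
  absolute agreement, single measures". All mean squares are retained in
  the result for audit. Degenerate inputs are handled explicitly: zero
  total variance raises `IccUndefinedError`; perfect agreement with
  between-patient variance returns ICC 1 with interval (1, 1). Missing
  data policy: pairwise deletion for VU-level tables, listwise for ICC.
  Tests verify the value against an independent sums-of-squares ANOVA
  oracle (statsmodels) to 1e−10 and the interval against pingouin's
  reference implementation.

## The phantom: what it emulates, and what it does not

The generator reproduces the *geometry and logic* of the imaging problem,
not MR physics. Defaults:

| parameter | default | meaning |
|---|---|---|
| grid / spacing | 72×480×9 at 1.25×1.25×4.4 mm | sagittal stack; 4 mm slices + 0.4 mm gap |
| compact test geometry | 36×240×5 at 2.5×2.5×4.4 mm | same anatomy, used by the test suite and acceptance script |
| bodies | 24 rounded slabs, 24×30×20 mm, 4 mm disc gaps | C2…S1 |
| lesions | ellipsoidal cosine bumps, 9×9×4.5 mm semi-axes, against the lower endplate | a mild lesion, roughly a tenth of the VU bone volume (Berlin grade ≈1) |
| intensities | background 0.10, marrow 0.35, lesion amplitude ≈0.15–0.55 (a.u.) | STIR-like contrast ordering |
| per-body motion | rotation ≤ 2°, translation ≤ 1.5 mm | inter-session posture micro-motion |
| global warp | 3 mm sinusoidal, wavelength ≈ spine length | posture/curvature change |
| noise | additive Gaussian, σ = 0.02 | ≈17:1 marrow SNR |
| atlases | 11, shape jitter 3%, own 2 mm warp, masks eroded 1.3 mm | an 11-patient atlas set with deliberate under-segmentation |

TP2 is constructed analytically as (global warp ∘ per-body rigid) applied
to the TP1 anatomy with lesion amplitudes swapped; the exact forward field
and its numerical inverse (fixed-point iteration; the warp's displacement
gradient is ≲0.08, far inside the contraction regime) are recorded, so
alignment can be tested against exact truth. Lesion amplitude ratios map
to the −2…+2 truth scale through fixed documented thresholds (ratio ≥ 2
dramatic, ≥ 1.25 mild, symmetric for decreases, with a 0.05 amplitude
floor); the mapping only needs to be monotone and fixed, since the
ordinal scale has no physical definition of "dramatic". The target's
TP1 anatomy is canonical (per-seed variation enters through lesions,
motion, warp, and noise) while atlases carry their own geometry jitter
and warp; this keeps every target→atlas mapping analytic, so segmentation
is testable without running a registration. Rejection contracts: a lesion
that cannot fit inside its host body, and per-body motion that makes
bodies overlap at TP2, both raise `PhantomError` with a diagnostic.

What passing phantom tests does **not** show: robustness to real
inter-subject anatomical variation, registration failure modes (5/30-level
exclusion rates in practice come from exactly this), pulse-sequence
artifacts, Rician noise (a noted extension; Gaussian is sufficient for
sign-recovery testing), partial-FOV stitching of upper/lower acquisitions
(a split mode crops overlapping subvolumes to exercise bottom-up labeling,
but stitching itself is out of scope), and the human factors of reading.

## Problem sizes

The test suite and acceptance script run on the compact geometry: one
shared 11-atlas set, 20 seeded phantom cases for the sign-recovery
Monte-Carlo, 100 random instances each for the majority-vote and ICC
oracle comparisons, and a 25-patient simulated cohort for the
difference-table and ICC machinery. These sizes were chosen to exercise
every code path with comfortable statistical margins while keeping a full
run in tens of seconds.

## Known limitations

* The change statistic is a crude surrogate for a trained reader; it
  detects net mean change and dilutes multifocal opposing changes within
  one VU (the quadrant-wise refinement used by SPARCC-style scoring would
  address this and is out of scope).
* The demons backend is a convenience for exploration; no claim is made
  that it matches a tuned production registration.
* Agreement statistics on simulated cohorts characterize the machinery,
  not clinical reader behavior; the cohort simulator's disagreement and
  miss rates are plausible but invented.
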