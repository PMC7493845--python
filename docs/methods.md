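# Methods

`aneufilt` detects intracranial aneurysms in 3D angiographic volumes as
bright, near-spherical structures attached to bright tubular vessels.  The
pipeline has five stages: preprocessing, per-target filter-parameter search
by Bayesian optimization, spherical-structure enhancement, adaptive
thresholding with region growth, and iterative removal for multiple
aneurysms.  This note records the model, the parameters that matter, the
numerical choices, and what the synthetic phantoms do and do not show.

## Enhancement filter

Local shape is read from the scale-space Hessian.  At scale `s` (voxels)
the Hessian of intensity `I` is the convolution of `I` with second
derivatives of a Gaussian of standard deviation `s`, multiplied by `s²` so
responses are comparable across scales.  Its per-voxel eigenvalues are
sorted by magnitude, `|λ1| ≤ |λ2| ≤ |λ3|`, and sign-adjusted (negated) so
bright blobs carry positive triples: a bright sphere has all three large
and positive after adjustment, a bright tube has `λ1 ≈ 0`.

The blobness response at cutoff fraction `τ ∈ [0.7, 1]` is

```
λρ = λ3                 if λ3 > τ·Λ
   = τ·Λ                otherwise
B1 = (2/3)·[ λ1²·λρ·(3/(2λ1+λρ))³ + λ1²/|λρ| + √(λ1·λρ) ]
Bp = (e^B1 − 1)/(e − 1)
```

forced to zero wherever any adjusted eigenvalue is negative (or `λ3 ≤ 0`):
the bright-sphere pattern needs all three positive, and admitting saddle
voxels (`λ2 < 0`) would both score non-blobs and make the response
discontinuous at magnitude ties.  `Λ` is the
*reference eigenvalue*: the volume-wide maximum of the adjusted `λ3`
searched across the whole scale family (a geometric grid spanning the
`s` box).  Using a single cross-scale reference is load-bearing: it makes
weak scales (whose strongest structure is far below the global maximum)
respond weakly, so the parameter search is scale-selective.  Normalizing
each scale by its own extremum instead makes every scale's best voxel look
equally good and the optimization degenerates to the finest scale.

`Bp` is deliberately not clipped to [0, 1] — an ideal unit-isotropic triple
scores `e + 1 ≈ 3.72` — because downstream thresholds are free parameters.
A `jerman_compat` switch substitutes the classical bounded volume-ratio
blobness for comparison runs.

Numerical choices:

- The sign mask is also the numerical guard: the first `B1` term has a
  pole at `2λ1 + λρ = 0`, reachable only from negative `λ1`.  A residual
  `1e−12` band guards the exact boundary, and the √ argument is clamped at
  zero.
- Gaussian-derivative kernels are moment-corrected sampled Gaussians:
  zero DC (constants map to exactly zero) and exact unit second moment.
  Naive sampling is badly aliased at sub-voxel `s` — at `s = 0.5` the
  uncorrected second-derivative kernel's DC sum is ≈ −0.56, which turns
  every bright plateau into a fake isotropic blob.
- `s` is interpreted in voxels and clipped below 0.5 (a Gaussian kernel
  under half a voxel is degenerate); anisotropic spacing is accepted but
  logged, and strongly anisotropic volumes should be resampled first.
- Responses within a face margin of `min(⌈2s⌉+1, 12)` voxels are zeroed:
  reflection boundaries fold structures that cross the field of view
  (vessels always do) into sphere-like artifacts.
- The per-voxel eigensolver is the closed-form trigonometric solution for
  symmetric 3×3 matrices, run as a compiled kernel; the whole
  Hessian–eigen–blobness pipeline is single precision (about 10× faster at
  ~1e−7 relative accuracy, orders below the filter's own discretization
  error).

## Parameter search

The two filter parameters `z = (s, τ)` are found per target by minimizing
the reciprocal response `f(z) = 1/(ε + max_x Bp(x; z))`, `ε = 1e−12`, with
Gaussian-process Bayesian optimization:

- Surrogate: constant-mean GP with ARD Matérn 5/2 kernel on inputs rescaled
  to the unit box; amplitude, per-dimension length scales and noise refit
  by marginal-likelihood maximization each iteration (two L-BFGS-B starts);
  `σ_n²` floored at 1e−10.
- Acquisition: closed-form expected improvement for minimization,
  maximized over a 2048-point scrambled-Sobol scan plus a Nelder-Mead
  polish from the best scan point.
- Initial design: 4 scrambled-Sobol points; total budget 50 evaluations by
  default (the phantom study uses 25 per round to keep runs short).
- Overexploitation safeguard: when the posterior standard deviation at the
  proposed point falls below `t_σ` (default 0.5) times the fitted noise
  standard deviation, the kernel amplitude is inflated — first by the
  current iteration index, then by successive factors of 10 — and the
  acquisition re-maximized, up to five retries, after which the last
  candidate is accepted with a logged flag.  The "multiply by the iteration
  count, then by 10" escalation is one reading of an ambiguous rule; it is
  a design choice here, not a claim about the only possible schedule.
- Everything is driven by one integer seed; two runs with the same seed
  produce identical traces.

Using the volume *maximum* of `Bp` as the loss scalar is itself a design
choice (the detection stage seeds at the global maximum, so the maximum is
the quantity being optimized).

## Detection loop

Per round: preprocess (first round only — a 3×3×3 reflection-padded median
filter then min-max normalization to [0, 1]), optimize `(s, τ)` on the
current image, build the response at the optimum, seed at the response
argmax, grow a 26-connected region (a voxel joins iff its response is at
least `α`·seed response, default `α = 0.5`, with an optional absolute
floor), and classify the target by comparing `V_mean` (default) or `V_max`
over the grown region against a threshold (strict inequality).  `V_mean`
is preferred because aneurysm responses are uniform while vessel-bump
responses are peaky.

A positive target is removed: a sphere at the target's center of mass with
radius equal to the largest bounding-box extent (the literal extraction
rule; a half-extent alternative is configurable) is zeroed, with a 2-voxel
cosine feather at the cut edge, and the sphere plus a 3-voxel margin is
excluded from all later rounds' responses and from the reference
eigenvalue.  Feathering and exclusion exist because a hard crater rim cut
through a bright vessel is itself a sharp sphere-like structure: without
them, every round after the first re-detects the previous round's cut
edges (measured as AUC ≈ 0.5 on phantoms).  The loop stops at the first
negative classification, when no bright-blob structure remains, or at the
round cap (default 5, comfortably above the clinical maximum of three
aneurysms per patient).  Each aneurysm therefore gets its own optimal
`(s, τ)`.

## Synthetic phantoms

The generator emulates the structure the detector assumes: one or more
bright curved tubes (vessels) crossing the whole volume, with soft-edged
bright spheres (aneurysms) placed tangent to a tube, plus noise.  Profiles
fall off as `2^(−(d/r)²)` so the half-maximum surface sits exactly at the
nominal radius.  Defaults: 96³ voxels, one vessel of radius 2–4 voxels,
aneurysm radii 3–8 voxels (at the clinical 0.4–0.6 mm spacing, 1 voxel
≈ 0.5 mm, so these correspond to roughly 3–8 mm lesions), aneurysm count
drawn 1/2/3 with clinical frequencies 127:16:2 when not fixed.

Geometry and noise choices that matter:

- Vessel centerlines are cubic splines through jittered control points that
  overshoot the volume faces, so tubes cross the field of view: an
  in-volume tube *cap* is a genuine bright sphere that real vessels never
  show.  Distance to the centerline is computed against a densely
  resampled polyline (0.1-voxel spacing), not a voxelized raster, because
  rasterized centerlines give scalloped tube surfaces with spurious
  fine-scale curvature.  Control-point jitter is moderate (±1/8 of the
  cross-section) so bend radii stay above the lumen radius, as for the
  main cerebral arteries in a ~5 cm field of view.
- A Gaussian reconstruction PSF (σ = 0.8 voxel) band-limits the object,
  and the additive Gaussian noise (σ = 0.03 on the [0, 1] scale) is passed
  through the same PSF and rescaled: detector noise in a reconstructed
  rotational-angiography volume is correlated, not voxel-white.  White
  voxel-scale noise would put spurious axial curvature on every tube at
  fine scales, breaking the tube-suppression property the filter's own
  theory assumes.

What passing on phantoms does *not* show: performance on real 3D-DSA with
bone-subtraction residue, bifurcations and touching vessels, beam-hardening
streaks, lesions far from spherical, or saturation plateaus.  The phantom
study is a scaled-down stand-in for a clinical evaluation, not a clinical
claim.

## Evaluation

Detections are scored at the lesion level: greedy one-to-one matching, a
detection is a true positive when its centroid lies within the truth radius
plus 1 voxel of an unmatched truth.  Precision, recall (sensitivity), F1
and FPR follow the standard definitions; undefined metrics are reported as
undefined, never as zero.  True negatives — needed for FPR and ROC — are
taken to be candidate targets examined and correctly rejected; this is a
stated convention, since lesion-level detection has no natural negative
class.  Curves sweep the classification threshold over recorded candidate
statistics; AUC is trapezoidal over the ROC (equal to the normalized
Mann-Whitney U).  The operating point reported by the benchmark is the
max-F1 threshold of the `V_mean` sweep, the conventional best-performance
point of a PR analysis.

The bundled phantom study runs 20 phantoms (three of them with two
aneurysms), 25 BO evaluations per round, 3 rounds per volume with candidate
recording, about 12 minutes on one CPU.  These sizes are the package's
default desk-scale study; they can be raised freely in the benchmark
config.

## Known limitations

- The detection loop stops at the first negative classification; a junk
  candidate scoring above threshold before a true aneurysm postpones, and
  a junk candidate below threshold hides, later true targets.  The
  benchmark's candidate recording sidesteps this for evaluation, but the
  deployed loop inherits it from the design.
- The removal radius rule (max bounding-box extent used as a radius) can
  excise large chunks of healthy vessel around a large target.
- The cross-scale reference eigenvalue makes the response of *everything*
  relative to the strongest blob in the image: a second, much fainter
  aneurysm yields proportionally weaker responses until the dominant one
  is removed (which is what the iterative strategy is for).
- `s` is in voxel units; physical-size priors (mm) require resampled or
  isotropic inputs.
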