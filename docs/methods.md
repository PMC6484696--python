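# Methods

`svrecon` reconstructs a high-resolution isotropic volume of a moving subject
(the motivating case: the fetal thorax on T2-weighted single-shot fast-spin-echo
MRI) from several overlapping stacks of 2D slices, each slice free to move
rigidly. This note records the models, the defaults and why they were chosen,
the numerical choices, and what the synthetic validation does and does not
establish.

## Forward model

Each acquired pixel is a point-spread-function (PSF) weighted average of the
underlying object under the slice's rigid transform, times a per-slice gain:

    y_ij = s_i · Σ_k m_ijk x_k + ε_ij,      Σ_k m_ijk = 1

* `x` — the unknown volume on an isotropic grid (0.50–0.75 mm; default
  0.70 mm, a balance between resolved detail and the size of the sparse
  coefficient matrix on a single CPU).
* PSF — separable anisotropic Gaussian in the slice frame: through-plane FWHM
  equal to the slice thickness (2.5 mm default; the standard slice-profile
  approximation for single-shot fast-spin-echo), in-plane FWHM 1.2× the pixel
  size (1.5 mm), truncated to exactly zero beyond 2.5 σ per axis. The
  truncation is part of the model: all quadrature of the PSF uses
  Gauss–Legendre nodes scaled to the finite support (Hermite rules would
  integrate the untruncated Gaussian and disagree with dense quadrature at
  the percent level).
* `m_ijk` — the PSF evaluated at output-voxel centres inside the moved
  support box of pixel (i,j), row-normalised. Pixels whose support leaks off
  the grid, or whose centre falls outside the mask, carry no coefficients.
* Rigid transforms: intrinsic Z-Y-X Euler angles (degrees) about the mask
  centroid, then translation (mm), world RAS coordinates. The centroid pivot
  keeps rotation and translation approximately decoupled for small fetal
  motions, which derivative-free optimisation relies on.

## Acquisition simulation (study conditions)

The simulator reproduces the acquisition protocol the method targets: 6–12
stacks (default 9) in three orthogonal orientations; 1.25 × 1.25 mm in-plane,
2.5 mm thickness, 1.25 mm overlap (slice step = 1.25 mm, 2× through-plane
oversampling); interleaved acquisition order (even slice positions then odd) —
single-shot multi-slice sequences acquire interleaved, which is what makes
motion between spatially adjacent slices realistic.

Motion is a per-slice random walk in acquisition time over all six rigid
parameters — drift 0.1 mm and 0.1° per slice step — plus persistent jumps
(probability 0.04 per step, amplitudes N(0, 2 mm) / N(0, 2°) per axis):
a fetus that is mostly quiescent but repositions abruptly and stays in the
new pose. With these defaults the raw median corner displacement across a
9-stack protocol is ≈3 mm (max ≈8 mm). Noise is additive Gaussian (σ = 3
intensity units against a body intensity of 100); magnitude (Rician) bias is
irrelevant at this SNR and the Gaussian keeps the residual model consistent
with the EM inlier component. A 2% log-normal per-slice gain jitter stands in
for inter-slice signal variation and exercises the gain-estimation stage.

## Digital thorax phantom

Ground truth is a bright ellipsoidal body (semi-axes 20/17/21 mm, intensity
100) containing dark vessels (intensity 10, black-blood contrast): a straight
descending aorta (radius 2.75 mm), a torus-segment transverse arch (2.5 mm)
with two branch stubs, and a straight SVC (2.25 mm) — approximately
late-gestation calibres in a scaled-down thorax. Partial-volume edges are
rendered by 3× supersampled occupancy; overlapping vessels combine by maximum
occupancy so shared voxels darken once. The body carries a smooth
heterogeneity texture (Gaussian random field, 2.5 mm correlation length, 8%
amplitude): real soft tissue is not uniform, and that texture is precisely
what makes individual slice poses observable — without it an ellipsoid plus
axis-parallel tubes leaves slice tilts and near-180° flips almost
unconstrained. Default grid: 96³ at 0.5 mm. Phantom noise σ = 2 models the
residual noise of a gated reference acquisition.

What the phantom does *not* emulate: cardiac chambers and pulsation, flow
effects, maternal-breathing non-rigid deformation, bias fields (available as
an option, off by default), and anatomy outside the thorax. Passing the
validation therefore shows that the pipeline recovers known geometry under
rigid per-slice motion at realistic contrast and noise — not that it handles
non-rigid physiology.

## Registration

All registrations maximise normalised cross-correlation (NCC): the problem is
mono-modal (acquired slices vs PSF-simulated slices of the same contrast), and
NCC is smooth, parameter-free and invariant to affine intensity scaling.
Optimisation is Powell's method over the six rigid parameters.

Slice-to-volume registration simulates the candidate slice from the current
volume through the PSF (Gauss–Legendre quadrature; the in-plane profile is
included at the finest level because dropping it measurably displaces the NCC
optimum) and proceeds coarse-to-fine: volume smoothing 3 → 1.5 → 0 voxels,
with a deterministic shrinking pattern search (steps 4 mm / 4°) ahead of the
first Powell stage to widen the capture range beyond line searches. Three
safeguards address the geometry of this metric:

* the comparison region (mask ∩ slice support) is frozen at each stage's
  starting pose — letting it follow the candidate transform would let the
  optimiser shrink the region onto flat anatomy and inflate NCC spuriously;
* a weak quadratic motion prior (3×10⁻⁵ per deg²/mm²) about the stage anchor
  keeps poorly-determined pose directions (tilts of slices through
  near-cylindrical structures) from wandering along flat NCC ridges;
* after each outer registration pass, slices that scored far below their
  stack's median similarity are retried from the poses of their temporal
  (acquisition-order) neighbours — motion is continuous in time, so these are
  typically capture failures after a sudden movement;
* the estimated pose trajectory of each stack is then median-filtered along
  acquisition time (window 5). True motion drifts only ~0.1 mm between
  consecutive acquisitions while independent per-slice registration errors
  are several times larger; the median filter suppresses that noise and, being
  an edge-preserving filter, keeps genuine jumps intact. This step roughly
  halves the median target registration error of the pipeline.

Stack-level initialisation registers every stack's 3D image to the scattered
average of all stacks. The average shares the frame of the mask; initialising
to the template stack image instead would shift the whole reconstruction by
the template's own mean motion.

Template selection ("least movement artifact") is the argmax of the mean NCC
between spatially adjacent slices — a declared, deterministic criterion
validated against simulated registration error; ties break to the lowest
stack index.

## Robust statistics and exclusion

Residuals e_ij = y_ij/s_i − ŷ_ij are modelled as a two-component mixture:
Gaussian(0, σ²) inliers against a uniform outlier component on the observed
residual range (floored at 1% of the intensity range so a near-perfect fit
cannot make the uniform density explode). EM re-estimates σ and the mixing
fraction by weighted maximum likelihood; the posterior p_ij weights every
pixel in the data term. Per-slice mean posteriors go through a second
two-class Gaussian mixture; a slice's weight w_i is its posterior for the
consistent class, and slices with w_i < 0.2 are excluded. The split is only
applied when the lower class is genuinely worse (class means separated by
> 0.1 with the lower mean < 0.6) — a tight all-consistent cluster must not be
cut in half. Per-slice gains are closed-form least squares, clamped to
[0.2, 5].

## Super-resolution update

    x ← x + α Σ_ij w_i p_ij m_ijk (y_ij/s_i − ŷ_ij) − α λ ∂R/∂x

R is a Huber-type first-difference penalty over 6-neighbourhoods whose
influence saturates for neighbour differences above δ — the gradient-descent
form of edge-preserving anisotropic diffusion, kept inside a single objective
so the clean-data fixed point is exact. Defaults: α = 1 (row-normalised
coefficients make the data-term column sums ≪ 1, so this is well inside the
stability limit; a divergence guard halves α if the misfit grows twice in a
row), λ = 0.05, δ = 5% of the robust intensity range, 4 outer iterations
(the EM-weighted misfit plateaus between the third and fourth) with 15
sub-iterations each and a longer final pass (40) so the output converges
after the closing gauge correction and exclusions. λ was set by oracle-pose
reconstructions of the default phantom (masked NCC 0.966 / 0.978 / 0.985 for
λ = 0.01 / 0.02 / 0.05): at black-blood contrast the stronger smoothing
suppresses propagated noise without measurable edge cost.

The solver runs on a mask dilated by 3 mm and the output is zeroed outside
the input mask: the anatomy/air edge just outside the region of interest
stays representable (otherwise boundary voxels absorb unfittable residuals as
a bright rind), while the masked-patch contract — voxels outside the input
mask are never written — holds exactly for the returned volume.

Loop order: each outer iteration refines intensities first (gains, EM, SR
steps) and then re-registers every slice against the sharpened estimate;
registration against the doubly-blurred scattered average measurably biases
poses. A final intensity pass follows the last registration so the output
reflects the final transforms.

Two closing steps precede that final pass:

* **Gauge fixing.** Per-slice registration never constrains the common-mode
  pose, so the frame drifts slowly (a degree and a fraction of a millimetre
  over the outer iterations). The input mask outlines the anatomy in the
  target frame, so the drift is estimated blindly by rigidly registering the
  reconstruction's smoothed supra-threshold occupancy to the smoothed mask
  indicator; the correction is applied to every slice pose and the volume.
* **Final robust exclusion.** Per-slice NCC between acquired and simulated
  pixels is a direct readout of residual misregistration; slices more than 3
  robust standard deviations (MAD) below the cohort median are excluded
  before the final intensity pass.

## Vessel-diameter measurement

Diameters are measured the way an observer works on a multi-planar
reconstruction: resample the plane perpendicular to the (known) centreline,
refine the lumen centre as the centroid of the dark plateau (an argmin is
ill-defined on a flat lumen), cast radial profiles at 0.05 mm steps, and take
the mean full-width-at-half-contrast between the lumen minimum and the local
background median. Half-contrast is a deterministic, testable stand-in for an
observer's edge judgement. A plane without a contrast dip (background minus
lumen < 25% of background) is flagged not measurable rather than returning a
number.

## Agreement statistics

* ICC: two-way random effects, absolute agreement, single measures (ICC(A,1))
  from the two-way ANOVA mean squares, with the McGraw–Wong F-based 95%
  interval. This is the form that matches inter-observer agreement of paired
  continuous measurements; with zero total variance the coefficient is
  undefined and flagged.
* Bland–Altman: bias with a t-interval, limits of agreement = bias ± 1.96·sd
  of the differences exactly, plus the paired-t p-value.
* Normality: Lilliefors-corrected Kolmogorov–Smirnov (parameters estimated
  from the data), table-based p-values (statsmodels).
* Wilcoxon signed rank: zeros dropped but tallied, mid-ranks for ties; exact
  two-sided p by dynamic-programming enumeration of the signed-rank null for
  ≤ 25 nonzero pairs (doubled mid-ranks are integers, so the distribution is
  a polynomial product), tie-corrected continuity-corrected normal
  approximation otherwise. Two-sided throughout.
* Identification summaries: percentages round half-up; head-to-head tallies
  use only items identified in both modalities; `score_table_from_counts`
  builds the deterministic table that realises published summary counts so
  count-derived percentages can be recomputed from first principles.

## Problem sizes and determinism

The validation experiment runs at 96³ × 0.5 mm phantom scale with 9 stacks
(≈360 slices) and a 0.7 mm reconstruction — sized so a full blind run
completes in minutes on one CPU core. Unit and property tests use smaller
grids (64³ × 0.75 mm phantom, ≤18³ toys for the least-squares oracle).

Every stochastic component draws from `numpy` generators seeded through
`SeedSequence([seed, stream, index])` (stream 0: phantom, 1: per-stack
motion, 2: per-stack noise), so one integer seed reproduces any experiment
bit-for-bit; the reconstruction itself contains no randomness. Known
limitations: rigid-only motion (non-rigid deformation is outside the model),
a fixed mask (not re-estimated per iteration), no bias-field estimation, and
registration accuracy that degrades for slices with little in-mask support —
such slices are down-weighted or excluded by the EM stage rather than
rescued.
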