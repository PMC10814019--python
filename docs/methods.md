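# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `choromvq`. It is written for a reader who wants to know what
the package actually computes and what passing its tests does and does not
demonstrate.

## Signal model for ultrafast Doppler ensembles

`synth.simulate_iq` produces post-beamformed compounded IQ data — a complex
cube (depth × lateral × slow-time) — as the sum of three components, all
finally blurred by an isotropic Gaussian point-spread function (default
σ = 1 px):

* **Tissue clutter.** `tissue_rank` (default 2) spatially smooth complex
  patterns (Gaussian-filtered white fields, smoothness 8 px), each multiplied
  by its own slow phase drift `exp(2πi f_k t)` with f_k near 1 Hz. The
  clutter therefore occupies exactly `tissue_rank` spatiotemporal singular
  components. Total clutter power is set by `clutter_to_blood_db`
  (default 40 dB above blood). The rank is deliberately *known and matched
  to the clutter filter's default `rank_low`* — with fixed-rank SVD
  filtering, a simulator whose clutter rank exceeds the cut leaves clutter
  behind, and one whose rank is below the cut lets the filter swallow blood.
  Real clutter has no exact rank; this is a simplification the synthetic
  study conditions accept, and the adaptive-threshold option exists for
  experiments beyond it.
* **Blood.** Complex speckle confined to the vessel lumen, unit stationary
  power, with per-pixel Doppler phase rotation at
  f_D = 2 v_axial f_c / c (v_axial from the rasterized velocity field).
  The speckle amplitude evolves as an AR(1) (Ornstein–Uhlenbeck) process
  whose correlation time defaults to the scatterer transit time through the
  PSF at the median lumen speed (`'auto'`; 10 ms at 10 mm/s and a 100 µm
  PSF). This matters: a speckle pattern frozen over the whole ensemble
  leaves the power-Doppler image with full exponential speckle statistics —
  dark nulls that fragment any binarized vessel — whereas transit-time
  decorrelation gives slow-time averaging the ~√N variance reduction it has
  physically. `'frozen'` is available for tests that need a static pattern.
* **Noise.** Complex white noise at `snr_db` (default 20 dB) below blood.

Doppler frequencies beyond ±frame_rate/2 alias; the simulator warns
(`AliasingWarning`) and proceeds, since aliased flow is a real acquisition
condition. Default acquisition follows the study protocol: 1000 frames at
1000 Hz, 16.5 MHz, c = 1540 m/s, 50 µm isotropic pixels on a 256 × 256 grid
(12.8 mm field — choroidal-lesion scale).

## Synthetic vasculature

`generate_vessel_tree` grows a binary tree breadth-first from a root near
the top of the field. Each segment is a straight chord perturbed by one sine
period orthogonal to it — the arc length has a closed quadrature form, which
is what makes the tortuosity ground truth testable. Planned bifurcation
angles are drawn uniformly from 60–120° (splitting symmetrically about the
parent heading), covering the ~100° mean bifurcation angles seen in tumor
vasculature. Daughter diameters satisfy d_p^γ = d₁^γ + d₂^γ *exactly*
(γ = 3, Murray's law, by default) with a random 40–60% flow split, so the
downstream Murray-deviation estimator can be validated against a true value
of zero. Blood speed scales as d^(γ−2) down the tree (flow conservation
under Murray splitting), 10 mm/s at the root. Segment lengths decay by 0.8
per generation; headings are steered back toward the field interior near
the boundary, and the boundary margin covers the root lumen radius.

`rasterize` renders the tree as the union of stadium-shaped dilations of the
centerlines (radius = diameter/2) on a pixel grid (centers at
(i + 0.5)·pitch, row 0 shallowest), assigning each lumen pixel the axial
velocity component of the nearest centerline sample. A tree that does not
fit inside the grid (lumen included) is rejected rather than clipped.

## Cohort simulation

`generate_cohort` draws per-participant biomarker vectors from
moment-matched marginals: Gaussian by default; shifted log-normal for the
right-skewed measures (τ has support ≥ 1, so τ − 1 is log-normal; NV is a
rounded log-normal); NB from a zero-inflated Poisson parameterized by its
mean and P(NB = 0) — the simplest family reproducing both the printed
moments and the branching-missingness fraction (P(NB=0) = 7/15 for the
benign arm, ≈ 0 for the malignant arm, whose mean of 8.9 makes Poisson
zeros negligible). MDmean/MDmax/BAmean/BAmax are set to missing exactly
where NB = 0. Columns are sampled independently: a cohort specification is
a set of marginals plus the missingness coupling, not a joint distribution,
so cross-column order constraints (Dmax ≥ Dmean) and range constraints
(Gaussian VD can graze 0) are not enforced on simulated tables. The
rank-based statistics downstream are unaffected; anyone needing physically
coherent records should use the end-to-end pipeline, where records come
from actual phantom measurements.

## Reconstruction

* **SVD clutter filter.** Casorati matrix (pixels × frames), implemented
  through the frames × frames Gram matrix (exact, and cheap since
  frames ≪ pixels). Components with 1-based index ≤ `rank_low` (default 2)
  and > `rank_high` (default 0.9·min(Npix, Nt), the noise cut) are zeroed.
  Energy bookkeeping satisfies Parseval: output energy = Σ retained σ².
* **Power Doppler.** Per-pixel slow-time mean of |IQ|².
* **Vessel enhancement.** White top-hat with a disk (default radius 8 px)
  suppresses smooth background, then multiscale Hessian tubularity: per
  scale σ ∈ {1, 1.5, 2, 3, 4} px (spanning ~100–400 µm at 50 µm/px),
  γ-normalized eigenvalues |λ₁| ≤ |λ₂| of the σ-smoothed Hessian
  (reflect boundary handling); response 0 where λ₂ > 0 (not a bright
  ridge), else exp(−R_b²/2β²)(1 − exp(−S²/2c²)) with R_b = λ₁/λ₂,
  S = √(λ₁²+λ₂²), β = 0.5, and c = half the maximum S over the whole image
  across all scales. A single global c keeps the structureness term
  comparable across scales — normalizing per scale would erase exactly the
  scale selection that lets a ridge of width σ₀ win at the matching scale.
  Output is the pixelwise maximum over scales.

The exact denoising/enhancement chain used clinically is not public in
operator-level detail; this chain is the package's own reproducible
realization of the same three stages, and every image carries a provenance
list naming each applied step and its parameters.

## Morphometry

* **Binarization**: Otsu threshold computed from ROI pixels only (fixed
  quantile as an option); constant ROI ⇒ empty mask; components smaller
  than 4 px removed. Thresholding inside the ROI matters — bright structure
  outside the lesion must not move the operating point.
* **Skeletonization**: topological thinning; skeleton pixels with ≥ 3
  8-connected skeleton neighbors are junction pixels; junction pixels
  within 2 px merge into one branch point (so two crossing vessels give one
  X-junction, not two adjacent Y-junctions); terminal spurs shorter than
  `prune_px` (default 4 px) are removed iteratively — note a drawn twig of
  n px becomes a skeleton spur ~2–3 px longer, since thinning extends it
  into the parent's interior. Junction clusters left connecting exactly two
  segments after pruning are dissolved and their segments merged. Segments
  are maximal node-free pixel paths; branch points are clusters with ≥ 3
  incident segment attachments (a loop counts twice).
* **Diameter**: 2 × Euclidean distance transform of the mask, sampled along
  the skeleton, × pixel pitch. On noise-free rasterized trees this recovers
  generated diameters within one pixel pitch, and NB matches the generated
  bifurcation count exactly (tested over seeds and tree sizes).
* **Tortuosity**: per-segment path length (Σ 1/√2-weighted steps) over
  endpoint chord. The first and last 3 px of each segment are trimmed
  first: thinning leaves short diagonal jogs at segment terminals which
  otherwise bias τ upward by ~1% — with trimming a straight band measures
  exactly 1, and a half-circle arc π/2 within 2%.
* **Murray deviation**: at each branch point, local diameters are averaged
  over the 5 segment pixels nearest the junction; the largest is the
  parent; MD = |d_p³ − Σ d_i³| / d_p³ (exponent configurable).
* **Bifurcation angle**: daughter directions are unit vectors along each
  daughter's first 5 skeleton pixels, anchored at the daughter's own
  junction-end pixel (the cluster centroid sits off the daughter axis and
  would bias angles); with > 2 daughters the maximum pairwise angle is
  reported, consistent with reading the angle off the dominant pair.
* **Fractal dimension**: dyadic box counting on the skeleton (bounding-box
  cropped), least-squares slope of log N(ε) vs log(1/ε). The skeleton (not
  the filled mask) is the default input — the filled variant is a config
  switch — validated on a line (1.0), a filled block (2.0), and a
  Sierpinski prefractal (log₂3).
* MD and BA aggregates are NaN with `measurable_MD_BA = 0` exactly when
  NB = 0; τ and D aggregate over segments, MD and BA over bifurcations.

## Statistics

* **Wilcoxon rank-sum**, two-sided: exact enumeration when n ≤ 20 without
  ties, else tie-corrected normal approximation with continuity correction
  (the defaults of the R implementation the field uses). Identical constant
  samples return p = 1.
* **AUC** = (wins + ½ ties)/(n₁n₂), malignant as positive class, orientation
  as-is. CI: stratified nonparametric bootstrap (resample within group),
  percentile 2.5/97.5, B = 2000 by default, seeded. Measured coverage at
  nominal 95% (binormal AUC 0.75, n = 21/15) is ~96%.
* **Firth logistic regression**: Newton iteration on the Jeffreys-penalized
  likelihood l(β) + ½ log det I(β), hat-corrected score
  U*_j = Σ (y_i − p_i + h_i(½ − p_i)) x_ij, step-halving, convergence at
  max |U*| < 10⁻⁶ (50 iterations, non-convergence flagged). Estimates stay
  finite under complete separation; the intercept-only model reproduces the
  closed form p̂ = (k + ½)/(n + 1).
* **Structural-missingness LRT**: full design {1, X1, X1·X2} with X1 the
  measurability indicator and X2 the observed values z-scored and filled
  with 0 where unobserved — the fill is provably irrelevant (X2 enters only
  through X1·X2, zero whenever X1 = 0; asserted over fills {0, 99, −7}).
  The null is the *constrained* intercept-only fit on the same design, with
  the penalty still using the full 3×3 information determinant (the
  penalized-profile construction): penalizing the null with its own 1×1
  determinant shifts the statistic by an O(log n) penalty mismatch and
  measured a type-I error of ~0.15 at n = 36, versus 0.040 for the
  constrained form. LRT = 2(l*₁ − l*₀) against χ² with df = number of
  freed, non-redundant columns (X1 ≡ 1 degrades gracefully to a 1-df test
  with a warning).
* **Correlations**: pairwise-complete Pearson; entries with < 3 complete
  pairs or a constant column are NaN.
* **Group analysis**: the 8 always-measurable biomarkers get the
  mean ± SD / Wilcoxon / AUC [CI] table; the 4 branching biomarkers get the
  missingness-LRT table; a thickness-restricted subset (≤ 2.5 mm by
  default) repeats the rank tests; p-values are reported unadjusted for
  multiple testing throughout, matching the study's analysis plan.

## End-to-end study and problem sizes

`pipeline.run_end_to_end` simulates a melanoma-like arm (5–12 bifurcations,
tortuosity amplitude 0.15–0.35 mm, root diameter 500–800 µm) versus a
nevus-like arm (0–2 bifurcations, amplitude ≤ 0.08 mm, 300–550 µm), each
phantom through raster → IQ → reconstruction → morphometry, then the full
statistics; 21 vs 15 participants by default, thickness drawn at the
printed group moments. Per-phantom and per-stage seeds derive from one
master seed; tables are byte-identical across reruns and a manifest records
the config hash, seed and version.

Default spatial/temporal sizes (256 × 256 px, 1000 frames) suit one-off
runs. The test suite and acceptance checks run the study at 128 × 128 px
and 200 frames (and the null-calibration reruns at 64 × 64 px, 100 frames,
8 vs 8) — at those sizes the six discriminative biomarkers still separate
the arms decisively and label-permuted or identical-generator nulls reject
at ≈ α, so nothing in the conclusions depends on the larger grid.

The minimum-detectable-diameter scan (`resolution.py`) places one straight
axial vessel (full Doppler projection) on a 128 × 64 grid at 50 µm/px,
simulates the full 1000-frame acquisition with rank-2 clutter at 40 dB and
20 dB SNR, runs the complete chain, and requires a single connected
skeleton segment covering ≥ 80% of the true centerline. Diameters of
150 µm — and in practice 100 µm — pass across seeds.

## Limitations

The simulator omits: eye motion (the dominant clinical artifact), depth-
dependent attenuation and PSF anisotropy, RF-level beamforming and angle
compounding, speckle spatial correlation beyond the PSF blur, non-exact
clutter rank, and 3-D geometry (trees are planar, so vessel overlap is
rendered as merged lumen rather than out-of-plane crossing). Cohort
simulation matches marginal moments, not joint structure, so simulated
correlation matrices reflect only the missingness coupling. Passing the
suite therefore demonstrates the correctness and calibration of the
*algorithms* under controlled conditions — not clinical performance on
restricted patient data, which the package has never seen.
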