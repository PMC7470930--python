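# Methods

## Data model

A *series* is a stack of planar contours traced on consecutive serial
sections. Contours are stored in pixels in a JSON file with the physical
calibration (`pixel_size_nm`, `section_thickness_nm`) in its metadata and
are converted to micrometres on load; section `k` sits at `z = k ·
thickness` with section 0 at z = 0. Traced objects form a hierarchy: spine
heads belong to a dendrite shaft, and each spine head owns at most one neck
object and its PSD objects. Validation is total: orphan references, kind
mismatches, cycles, out-of-range section indices and non-positive
calibrations all raise typed errors at load or write time.

The image y-axis points down (image convention); all polygon areas are
taken as absolute values so vertex orientation never flips a sign.

## Measurement conventions and their biases

The estimators follow the serial-reconstruction conventions of
Reconstruct-style tracing. They are deliberately *not* corrected toward
smooth-surface values, because comparability with the conventional numbers
is the point; the biases are stated instead.

* **Volume** = Σ (contour area × thickness), one term per traced section
  (rectangle rule, no interpolation between sections). For a convex solid
  whose position relative to the section grid ("phase") is random, the slab
  sum is unbiased on average over phase; per-object error for a sphere of
  radius r is O((t/r)²). A thickness ladder (0.1, 0.05, 0.025 µm) converges
  monotonically to the analytic sphere volume (tested).
* **Surface area** = Σ (perimeter × thickness), plus the two extremal
  contour areas when end caps are on (default). The lateral term converges
  to ∫ circumference dz, which for a sphere is π²r² — a factor π/4 *below*
  the true 4πr². This stair-step bias is a property of the convention and
  is documented rather than corrected; shapes closer to z-aligned cylinders
  are nearly unbiased.
* **PSD area** = thickness × summed in-plane length of the open PSD traces.
  Exact in the flat limit (the chord integral of a disc of radius ρ cut
  transversally converges to πρ²); for a curved cap on a spherical head it
  underestimates by the average ratio of circle radius to sphere radius
  (order 5–10 % at realistic head sizes). PSD area enters the analysis
  through correlation and classification, which are insensitive to this
  monotone compression.
* **Dendrite length** = 3D polyline length through per-section shaft
  contour centroids (area-weighted within a section; no spline smoothing).
  This requires the dendrite to run transverse to the cutting plane, which
  matches how the stacks are acquired (hundreds of sections per ~10 µm
  dendrite). The polyline misses up to one section's worth of length at
  each flat-cut end (≲1 % at study scale).
* **Neck length**: when an explicit open neck polyline is traced, its 3D
  path length is used. Otherwise (the common case for solid neck contours)
  a deterministic anchor surrogate is used: distance from the measured head
  centre to the nearest point of the shaft axis, minus the head radius
  (from the measured volume) and the local shaft radius (median
  equivalent-circle radius of the shaft contours), clamped at 0 for sessile
  spines. The original bench protocol for this measurement is manual and
  not reproducible from traces; the surrogate is this package's design
  choice.
* **Spine density** = spine count / dendrite length; multiplying back
  recovers the integer count exactly.

Spines whose head reaches the first or last section are flagged
`touches_boundary`; the default `boundary_policy="exclude_touching"` drops
them from statistics because truncated heads bias volume low. The source
convention for such spines is unknown; `include_all` is available.

## Classification

* **Small vs large** (thin vs mushroom): head volume ≤ 0.04 µm³ → small.
  The cutoff is the adult median head volume in the reference data; the
  printed small and large ranges both include 0.040, so the boundary is
  genuinely ambiguous — ties go to small, fixed here for determinism.
* **Perforated vs macular PSD**: purely trace-topological. A PSD is
  perforated iff (a) some section holds ≥ 2 mutually disjoint traces of
  that PSD, or (b) the section-adjacency graph of its traces (edges between
  spatially close traces on consecutive sections) contains a cycle — the
  doughnut-shaped PSD that rings an untraced hole. Convex single-component
  caps can never trigger either branch (proved by the Cauchy–Schwarz bound
  on the cap-slice geometry and tested exhaustively over axis
  orientations).
* Percentages are rounded half-up to one decimal, fold changes to two —
  the reporting precision of the field.
* Head-volume histograms use left-closed right-open bins of width 0.04 µm³
  by default; relative frequencies sum to 1.

## Statistical battery

Normality is assessed per sample by Shapiro–Wilk at α = 0.05 (constant
samples count as non-normal). Two groups: both normal → two-sided pooled
Student's t; otherwise two-sided Mann–Whitney U, asymptotic without
continuity correction (identical samples then give p = 1 exactly). Three or
more groups: all normal → one-way ANOVA with Bonferroni-adjusted pairwise t
tests; otherwise Kruskal–Wallis with Bonferroni-adjusted Dunn rank tests
(pooled midranks, tie-corrected variance `N(N+1)/12 − Σ(t³−t)/(12(N−1))`).
Adjusted p-values are capped at 1. The gate is applied per comparison: one
non-normal group sends the whole comparison down the nonparametric path.

The two-sample Kolmogorov–Smirnov test uses the asymptotic Smirnov
distribution; its statistic equals the brute-force maximum ECDF gap exactly
(tested for n ≤ 20 with ties). Spearman correlation uses midranks and
equals Pearson on ranks to 1e-12. Type-I error of both gated paths is
0.05 ± 0.02 over 1000 seeded null replicates (tested).

Units of analysis: spine density is per-dendrite; head volume, neck length
and PSD area are per-spine. Both framings are available from the exported
tables.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, at
the scale of the reference study (eight groups: two genotypes × four ages;
7–11 dendrites per group, 65 total; section thickness 50 nm, pixel size
4.5 nm — within the stated 40–50 nm acquisition range, one constant per
series).

* **Dendrite**: a tube of radius ~0.3 µm around a z-monotone random-walk
  axis (tilt ≤ ~17° from the milling direction, step 0.05 µm), arc length
  drawn per group from the printed mean with sd = SEM·√n, clipped to the
  observed 5–25 µm range. Spine count ~ Poisson(density × length).
* **Head volume**: lognormal matched to the printed group mean and median
  (`mu = ln median`, `sigma = √(2 ln(mean/median))`). The family is not
  stated in the source; lognormal is the standard model for right-skewed
  spine volumes with mean ≫ median, and the closed form reproduces both
  printed moments exactly (verified by Monte Carlo).
* **Neck**: truncated normal ≥ 0.05 µm with printed mean and SEM-derived
  sd, realized as a cylinder (sphere-swept segment) protruding radially
  from the shaft; the head centre sits at shaft radius + neck length + head
  radius from the axis, which is what the anchor surrogate measures.
  Recovery tests compare against the truncated-distribution mean.
* **PSD**: spherical cap on the head, facing away from the shaft, with
  target area `c · V^b ×` lognormal(0, σ) noise; defaults c = 1 µm²/µm³,
  b = 1 (pure linear coupling, matching the observed linear PSD–volume
  relation), σ = 0.3, which yields per-group Spearman r ≈ 0.95 at study
  n. Caps are clamped to at most the polar angle 126° of the head sphere.
* **Perforation**: Bernoulli with p = logistic(b₀ + s·ln V), s = 1.5 by
  default so perforated PSDs concentrate in large spines; b₀ is calibrated
  by Gauss–Hermite quadrature so the *marginal* rate equals the configured
  group percentage (with s = 0 the rate is the intercept's logistic
  directly). Perforated caps are annuli whose central hole is sized to span
  at least one section plane (hole radius ≥ 1.2 t where the head allows),
  so the discontinuity survives slicing and both detection branches fire.
* **Slicing**: analytic cross-sections — circles for heads, discs for the
  shaft around the interpolated axis, unions of sphere cross-sections for
  necks (shapely), exact circular arcs for PSD caps. Circles are
  polygonized with chord sagitta ≤ pixel size and an area-preserving radius
  correction, so polygon area equals disc area exactly and volume recovery
  is unbiased. The stack is padded by one section on every side, so
  synthetic spines never touch the stack boundary. Output is byte-identical
  for a fixed (config, seed) pair.

What the generator does **not** emulate: manual tracing noise and
inter-rater variability, non-spherical head shapes (ellipsoidal, cup), true
stubby/filopodial morphologies, within-dendrite correlation of spine
properties (spines are exchangeable within a group), section-to-section
alignment jitter, and membrane-contrast limitations. Passing recovery
tests therefore demonstrates correctness of the measurement conventions and
statistics on idealized geometry, not robustness to segmentation error.

## Problem sizes and numerical choices

The study-scale preset (65 dendrites, ~1300 spines, ~250 sections per
series) runs the full generate–measure–analyze cycle in well under a
minute. Null-calibration simulations use 1000 replicates (two-sample and
omnibus paths at n = 20 and 4 × 10); power checks use 200 replicates. All
randomness flows from one master seed through `numpy` `SeedSequence`
spawning; identical seeds give identical files and reports. Degenerate
inputs follow fixed rules: n = 1 summaries report SEM 0 with a logged
warning, zero-length PSD traces contribute 0 with a warning, sub-3-vertex
cross-sections are dropped with a warning, and empty PSDs classify as
macular.
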