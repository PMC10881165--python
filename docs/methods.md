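# Methods notes

This note records the models, conventions, parameter defaults, and design
choices behind `svquant`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Geometry and units

All annotation geometry is carried in nanometres, with y increasing from
the axolemma into the axoplasm; files may store µm (declared in the JSON
header) and are normalized on read. Images carry physical calibration
(`pixel_size_um`, `frame_interval_s`) supplied by the caller, since plain
TIFF fixtures hold none.

## Morphometry

* **Vesicle classification.** A vesicular profile is a cisterna
  (presumptive endosome) iff its outer diameter strictly exceeds 100 nm;
  100 nm exactly is an SV. Annotated diameters are used as-is, with no
  correction for section-cap geometry.
* **Exposure regions.** Distance from the injection site maps to
  condition as: > 400 µm control, < 140 µm high concentration, otherwise
  low. The published bands leave (140, 150) µm unassigned; the gap is
  folded into the low band, the conservative choice (it can only shrink,
  never inflate, a concentration effect).
* **PM evagination.** Arc length along the traced axolemma from the AZ
  edge to the first point at 1 µm straight-line distance, with linear
  interpolation on the crossing segment; left and right sides averaged.
  A trace that never reaches the 1 µm shell raises a measurement error
  naming the synapse rather than silently truncating.
* **Total membrane.** The printed totals come from a formula defined in
  earlier work that the source text does not restate; the default
  `sphere_sv` convention here is a re-derivation: SVs and free coated
  vesicles contribute spherical surfaces π·d², planar traced structures
  contribute length × 70 nm section thickness. It reproduces the printed
  unstimulated-control total within ~4% and all printed component
  recombinations within ~15-20%; a `planar_all` convention (everything as
  profile × thickness) is selectable for sensitivity analysis.
  Membrane-attached coated pits (stages 1-3) are excluded from both the
  sphere term and PM length and reported separately, since their
  apportionment is unstated.

## Spatial statistics

* **AZ distances.** The AZ polyline is resampled uniformly in arc length
  at 5 nm and each SV centre is matched to the nearest sample point
  (KD-tree), bounding the error by 2.5 nm against the exact segment
  projection. Distance histograms use half-open 50 nm bins.
* **Nearest neighbours** are computed within a synapse section only.
  Sections with fewer than two SVs are excluded from NN statistics;
  duplicate coordinates yield zero distances with a warning.
* **Two-summed-Gaussian fit.** Bounded least squares with five starts
  (method-of-moments initialization plus seeded perturbations); components
  are reported ordered µ₁ ≤ µ₂. Single-Gaussian data are a nested
  special case — one component absorbs the mass and the fit is accepted.
  Non-convergence returns a flagged result, never an exception.
* **Log–log ellipse.** Base-10 logs of distances in µm; zeros are offset
  by half the measurement resolution (2.5 nm). Semi-axes are 2σ
  (2·√eigenvalue) by default. Neither the log base nor the σ multiple is
  fixed by the source text, so ellipse *areas* are comparable only within
  a configuration; all cross-condition conclusions rest on orderings, not
  magnitudes. Note that the eccentricity of a nearly isotropic cloud
  converges to zero only at rate n^(-1/4) (the covariance eigen-split is
  O(n^(-1/2))), so isotropy checks need very large n: the symmetry-limit
  test uses n = 10⁷, where the sampling floor sits near 0.02.
* **Bootstrap.** Percentile 95% CIs over ellipse refits of 2000 point
  pairs resampled with replacement per replicate, 1000 replicates by
  default, fully reproducible under the seed.

## Colocalization

* **Costes thresholds.** The inter-channel regression is fit over all
  pixels; the reference threshold scans every distinct intensity
  downward (a 256-level grid for float images) and stops at the first
  level where the below-threshold PCC ≤ 0. If the PCC never crosses zero
  the minimum intensity is returned flagged — this happens when the
  "background" itself is spatially structured, e.g. when pixels outside
  the cell are included, which is why analyses run within the axon mask
  as the ROI protocol prescribes.
* **Manders coefficients.** M1 = Σa over (a > Tₐ ∧ b > T_b) / Σa over
  (a > Tₐ), and symmetrically M2. The numerator is gated on both
  channels, which keeps the coefficients in [0, 1] and makes
  M1(A,B) = M2(B,A) exact.
* **Peak localization** on line profiles uses the centroid of the
  samples within 5% of the maximum: exact for plateaus (tie rule) and
  symmetric peaks, robust to single-sample noise on flat tops.
* **Density partition.** Two-class k-means on marker intensities within
  the axon mask (10 restarts, seeded); the brighter class is the synapse
  mask. Edge pixels of a synapse carry partial signal but fall in the
  axoplasm class, which biases the recovered axoplasm:synapse ratio
  upward by ~2-3 percentage points at realistic blob sizes — within the
  5-point recovery tolerance, but worth remembering when interpreting
  small ratios.
* The bleed-through correction median-filters (3×3) both channels before
  subtracting the stated fraction of the source channel, clipping at 0.
  The kernel size is a package choice; the protocol does not state one.

## Kinetics

* **Destain fits.** I(t) = A·exp(−(t−t₀)/τ) + C on background-subtracted
  data restricted to the stimulation window, time origin at stimulus
  onset, SE of τ from the fit covariance. Non-decaying traces are
  reported with τ = 10⁶ s and flagged, mirroring how unreleasable pools
  print as enormous τ ± SE. With only ~1τ of data and a free baseline,
  the least-squares τ estimator is right-skewed (mean bias ~7% at 5%
  noise even for a reference implementation); accuracy claims are
  therefore stated for windows of ≥ 2τ, where the estimator is unbiased
  to < 2%.
* **Variance tests.** Two groups: F ratio of the larger to the smaller
  variance with a two-sided p. More groups: Brown–Forsythe
  (median-centred Levene).
* **Ratio stack.** Frame ÷ mean of the 10 preceding frames, first 10
  frames omitted, denominator floored at 1% of the movie median.
* **Mobile puncta.** Difference-of-Gaussian spot detection per ratio
  frame (spot σ 0.5 µm, candidate gated at ratio ≥ 1.3), deterministic
  greedy nearest-position linking with a gate of 1.5 µm/s × Δt (slightly
  above the observed 1.2 µm/s speed ceiling), merging of runs split by
  ≤ 3 missed frames, and two track-level criteria: ≥ 5 *consecutive*
  detection frames and net displacement > one spot radius (2σ), so
  blinking stationary spots never count. Track speeds are measured over
  ≥ 4-frame windows so localization jitter does not inflate them.
  Counting is restricted to tracks starting within the stated window
  (200 s; the 50 µm axon length is the default field of view).
  *Limitation:* at low SNR (~4), satellite detections around a genuine
  mover can split into duplicate tracks, overcounting movers by up to
  ~50% while false positives away from real movers remain ≈ 0; counts at
  SNR ≥ 10 are exact on synthetic ground truth.

## Synthetic data

The generator emulates the *statistical structure* the analyses consume,
not the imaging physics:

* **Populations.** Per synapse: an AZ polyline of ~1 µm; a main SV
  cluster placed by hard-core (one vesicle diameter) rejection sampling
  under a half-Gaussian envelope above the axolemma, whose spread
  inflates by 10% steps under crowding (dense clusters swell rather than
  overlap — this also bounds the cluster extent at ~4σ); a dispersed
  fraction of SVs in compact microclusters of ~3 vesicles placed 0.6-2 µm
  away; PM traces whose evagination length is solved by bisection to hit
  the target; cisterna/CCPV records from truncated normals. Truncated
  draws are *mean-matched* (the location parameter is solved so the
  truncated mean equals the specified mean), so population means recover
  the preset values within Monte-Carlo error. Preset means and SDs encode
  the published group means and SEM·√n of the stimulated and unstimulated
  series; the WT-like SV count is the published pooled count divided by
  its synapse count. Presets are study conditions, not tuning knobs.
* **Images** emulate the IF analysis ROIs: a ~25 µm axon band containing
  eight ~1.2 µm synapse discs (≈15% of the band area), a controllable
  colocalized fraction, channel offset, bleed-through, and true
  axoplasm:synapse density ratio; noise is photon-counting (Poisson)
  with gain set so the synaptic peak SNR equals the requested value —
  Poisson noise is nonnegative, so no clipping bias enters density
  estimates. Ground-truth masks and ratios are returned alongside.
* **Movies**: stationary SV-cluster spots decaying with per-ROI τ after
  stimulus onset, movers on straight tracks at stated speeds (≤ 1.2
  µm/s), Poisson shot noise plus Gaussian read noise scaled to SNR.
* **What passing tests do not show.** Real micrographs have segmentation
  error, anisotropic point-spread functions, sectioning artifacts, and
  SV packing correlations beyond a hard core; real axons bend and vary
  in width. Recovery of generator parameters demonstrates the estimators
  are correct and unbiased under the stated noise models, not that those
  models exhaust real variability.

## Numerical conventions

Histogram bins are half-open [lo, hi) with the maximum value falling in
its own bin; ties in peak localization resolve to centroids; the Costes
scan takes the *first* threshold (scanning downward) with PCC ≤ 0
without interpolation; k-means and every stochastic routine accept an
explicit seed and are deterministic given it; bootstrap CIs are
percentile-based. Degenerate inputs (collinear clouds, flat traces,
constant channels, < 2 SVs) return flagged results or raise errors naming
the offending record — they are never silently dropped.

## Simulation sizes

Default problem sizes were chosen so the full validation battery runs
comfortably on a single CPU: population recovery at 500 synapses, sweep
and ordering checks at 40 synapses per condition, movie-based checks on
128 px × 110-230 frame movies, bootstrap determinism at 100-150
replicates. All are package choices encoded in the tests and the
acceptance script, and scale up linearly if more precision is wanted.
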