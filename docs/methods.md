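# Methods

`aoflio` analyzes time-correlated single-photon-counting (TCSPC) fluorescence
lifetime images of the photoreceptor layer, as produced by adaptive-optics
fluorescence lifetime ophthalmoscopy (AOFLIO).  The core question it serves:
can subpopulations of cones with different *functional* signatures — the
sparse S-cone submosaic versus M/L cones, plus the surrounding rods — be
separated from their fluorescence decays, even when their fitted mean
lifetimes are indistinguishable?  The answer pursued here is the phasor
method: a model-free Fourier representation of each decay in which
mixtures of fluorophore environments separate geometrically.

## Data model

A *decay cube* holds one photon-arrival histogram per pixel: `counts[row,
col, bin]` with 256 bins spanning one laser period (80 MHz repetition rate,
bin width 1/(80 MHz · 256) ≈ 48.8 ps).  Cubes travel in an HDF5 container
(`/counts`, `/irf`, attributes `repetition_rate_hz`, `n_bins`,
`bin_width_s`); ROI masks are 16-bit label TIFFs with a `(label, kind)` CSV
(`cone` or `rod_region`).  Coordinates are 0-based `(row, col)` from the
top-left.  Repeated exposures of the same retinal patch are co-aligned by
integer-pixel circular cross-correlation of intensity images (sum over bins)
and cropped to the overlap; photon histograms are never resampled
sub-pixel, since interpolation would destroy their Poisson character.  No
raster-desinusoiding correction is applied.

## Phasor transform and IRF correction

For a decay `d[k]` the phasor at the m-th harmonic of the repetition rate is

    g = Σ d[k] cos(ω t_k) / Σ d[k],   s = Σ d[k] sin(ω t_k) / Σ d[k],

with ω = 2π m f_rep and bin-center times t_k = (k + ½)Δ.  Bin centers halve
the leading-order discretization phase bias.  Mono-exponential decays lie on
the universal semicircle (g − ½)² + s² = ¼; any mixture lies strictly
inside; the transform is linear, so an ROI's phasor is the photon-weighted
mean of its pixels' phasors (these are tested as exact invariants).

The instrument response function (IRF) enters by periodic convolution.  In
phasor space that is a complex multiplication, so correction is the complex
division z_decay / z_irf.  One exact-arithmetic subtlety: with bin-center
times the discrete convolution theorem carries a residual half-bin phase
e^{−iωΔ/2} (~0.012 rad at 256 bins), which would dominate the error budget
of the correction.  The IRF *reference* phasor is therefore computed on bin
left edges (t_k = kΔ); with that convention the complex division inverts
periodic convolution exactly for binned data, and round-trip tests hold at
1e-6 (they hold at machine precision in practice).

Two closed forms serve as oracles: the continuous biexponential phasor
(intensity-weighted combination of component semicircle points, weights
a_iτ_i) and an exact *discrete* form for the bin-integrated, period-wrapped
biexponential — a geometric-sum expression `(1−E)e^{iωΔ/2}/(1−E e^{iωΔ})`,
E = e^{−Δ/τ}, per component.  The discrete form is what the transform of a
noise-free rendered decay must reproduce to machine precision; the
continuous form is approached with O((ωΔ)²) discretization error and is
used with correspondingly looser tolerances (3e-3 at ωτ = 1).

## Synthetic retina

No public AOFLIO dataset exists, so a simulator with complete ground truth
stands in.  It emulates:

- **Mosaic geometry** — a jittered hexagonal cone lattice (default spacing
  16 px on a 253 × 300 field, ≈330 cones, comparable to the ~348 cones per
  field in published AOFLIO data; jitter SD 0.5 px; cone radius 3 px).  A
  requested fraction (default 12%) of cones are labeled S by random
  sequential selection with a lattice-adjacency exclusion, reproducing the
  semi-crystalline S submosaic in which S cones are rarely neighbors.  Rods
  fill all interstitial pixels, grouped into per-lattice-cell Voronoi tiles
  mirroring the arbitrary rod-region outlining of real analyses.
- **Decay physics** — per-class biexponential kinetics, bin-integrated over
  one period with periodic wrap-around (incomplete decay at 80 MHz),
  circularly convolved with a Gaussian IRF (FWHM 150 ps, centered at bin
  10), scaled to a per-cell photon budget, and Poisson-sampled per
  (pixel, bin).
- **Nuisance structure** — per-cell lognormal brightness variability
  (σ = 0.12, mean 1) and optional optical crosstalk mixing a fraction of
  each cell's decay with its lattice neighbors' brightness-weighted decays
  (default 0).
- **Photodamage** — a selective S-cone damage mode: brightness divided by
  2.6 (the published fluorescence drop of damaged cones) and both lifetime
  components multiplied by 0.6, which moves the damaged-cone phasor toward
  (1, 0) as observed in vivo.

Default kinetics are synthetic: real per-class decay parameters are
unpublished (only mean-lifetime summaries exist).  They were chosen once to
embody the study's defining geometry and then frozen:

| class | a₁ | τ₁ (ps) | τ₂ (ps) | τ_m (ps) | photons/cell |
|-------|-----|---------|---------|----------|--------------|
| M/L cone | 0.70 | 150 | 1100 | 435.0 | 1e4 |
| S cone | 0.85 | 150 | 2050 | 435.0 | 1e4 |
| rod | 0.85 | 90 | 850 | 331.5 | 8e3 (per tile) |

The two cone classes share the same amplitude-weighted mean lifetime
*exactly* — the in vivo finding the simulator must emulate is that τ_m does
not discriminate cone classes (448.6 ± 290 vs 437.1 ± 254 ps, not
significant) — while their intensity-weighted phasors are far apart
(≈(0.63, 0.37) vs (0.82, 0.34) after IRF correction), because the phasor
weights components by a_iτ_i rather than a_i.  Rods sit nearest (1, 0).
What passing tests therefore show is that the *pipeline* separates classes
whose τ_m is uninformative; they do not validate the specific kinetics
values against biology, and the simulator omits optical PSF blur, eye-motion
distortion, desinusoiding artifacts and vessel shadows, all present in real
data.  Real-data performance is expected to be worse than the near-perfect
synthetic figures.

## Biexponential fitting

Per-pixel fitting follows the conventional TCSPC workflow: decays are first
summed over a 5 × 5 kernel (truncated at image edges) to raise counts, then
fit with d[t] = a₁e^{−t/τ₁} + a₂e^{−t/τ₂}, discretized as bin integrals,
circularly convolved with the IRF, plus a constant background ≥ 0.  The fit
maximizes the Poisson likelihood — `scipy.optimize.least_squares` on signed
square-root deviance residuals — rather than Gaussian-weighted least
squares: with 1e5 photons spread over 256 bins many tail bins hold 0–2
photons, where Neyman weighting (1/max(d,1)) measurably biases τ_m (≈14%
median error in our trials, vs <1% for the likelihood fit).  Internally the
optimizer works in O(1) units (amplitude relative to the total, lifetimes in
ns); lifetimes spanning 1e-10 s next to 1e5-scale amplitudes otherwise
cripple the trust-region scaling.  Initialization is τ₁ = 100 ps,
τ₂ = 1000 ps, 50/50 amplitude split, with up to 5 jittered restarts from a
fixed restart seed; components are ordered τ₁ ≤ τ₂ post hoc; non-convergence
is flagged with χ² = ∞.

Goodness of fit is the reduced Pearson statistic Σ(d−m)²/m over bins with
expected counts ≥ 5 (the classic validity rule), whose expectation is 1 for
a correct model at any count level; an under-specified single-exponential
model on biexponential data inflates it well past 1.5.  The mean lifetime
τ_m = (a₁τ₁ + a₂τ₂)/(a₁ + a₂) and the ratios a₁/a₂, τ₁/τ₂, %a₁ are
reported per ROI as means over member pixels.

## Clustering and S-cone calling

Cone phasors from one image are clustered by a Gaussian mixture model with
diagonal ("orthogonal") covariances, seeded by k-means (fixed seed), EM to
tolerance 1e-6 or 500 iterations, hard assignment by maximum posterior.  The
smaller final cluster is Cluster 1 and its members are the putative S cones;
an exact size tie is broken toward the cluster with smaller mean g (nearer
the origin, hence longer lifetimes).  k = 3 is available for multimodal
phasor plots — after fitting, the component with smallest mean g is kept as
the S candidate and the other two are merged — and is also tried
automatically if EM fails at k = 2.  Degenerate inputs (or failure at both
k) produce a single-cluster result flagged not-converged, from which no
S-call is made, mirroring the exclusion of non-separating locations in
practice.  Rod regions are never clustered with cones; they are summarized
separately as the third cluster.

## Cross-exposure comparison

Co-registered exposures share mask labels, so ROI matching is identity on
shared labels.  Repeatability tabulates day-1 vs day-2 S-calls into a 2 × 2
confusion with sensitivity n₁₁/(n₁₁+n₁₂) and specificity n₂₂/(n₂₂+n₂₁),
computed in exact rational arithmetic with half-even display rounding to one
decimal.  The damage-prediction scheme scores the baseline Cluster-1 call
against post-damage hypofluorescence; its "sensitivity" conditions on the
baseline call (Cluster-1 cones that did vs did not darken), a
positive-predictive-style figure matching how the in vivo result is
reported.  Hypofluorescent cones — identified by eye in the original
workflow — are detected here by a stated rule: a cone is dark when its
summed intensity falls below 0.5× the median of its 6 nearest cone
neighbors, the threshold sitting between the 2.6-fold damage drop (0.385×)
and ordinary brightness variability.

## Statistics

Cluster mean coordinates are compared with Hotelling's T²: the paired
(dependent) form T² = n m̄ᵀS_D⁻¹m̄ on per-ROI coordinate differences with
F = T²(n−p)/(p(n−1)) on (2, n−2) degrees of freedom, and a pooled-covariance
independent form for unpaired cluster contrasts (the in vivo description
does not fully specify which; both are provided, paired being appropriate
for matched ROIs).  Identical samples return T² = 0, p = 1; a singular
difference covariance with nonzero differences is an error.  T² is invariant
under common rotation of both coordinate sets, as a phasor statistic should
be.  Test–retest agreement of scalar summaries uses the intraclass
correlation coefficient; the variant is fixed to two-way random effects,
absolute agreement, single measures — ICC(2,1) — matching repeated
measurement of the same locations, and the variant label is always reported
(pingouin's ICC(A,1) serves as an independent cross-check in the tests).
MANOVA-style eccentricity analyses are out of scope; a paired t-test
convenience wraps scipy.  α = 0.05 throughout.

## Problem sizes and numerical choices

The shipped test and acceptance runs use the full default field
(253 × 300 × 256) with 20 independent scenes for end-to-end metrics, 100
simulated ROIs at 1e5 photons for fit recovery, 10,000 null replicates
(n = 15 pairs) for the Hotelling type-I calibration, and 1000 renders of a
reduced 60 × 60 × 32 scene for the Poisson dispersion check.  All stochastic
stages are seeded; reports carry a configuration hash so any run can be
reproduced bit-for-bit.  Known numeric edge cases: all-zero decays raise
rather than return a phasor; IRF phasors with modulus ≤ 1e-9 are rejected
as ill-conditioned; registration ties are broken by smallest |dr|+|dc|,
then dr, then dc.
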