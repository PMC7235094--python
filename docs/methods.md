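# Methods

`nanosyn` quantifies excitatory (and tripartite) synapse organisation in
punctate fluorescence images of nervous tissue, at two scales: whole
postsynaptic densities (PSDs, the PSD95-marked scaffold of excitatory
synapses) in diffraction-limited images, and the ~140 nm PSD95
nanoclusters (NCs) that compose them in gated-STED images.  This note
describes the analysis model, the synthetic data that validates it, and
the numerical choices that matter.

## The analysis chain

**Detection.** Each channel is processed as: rolling-ball background
subtraction → Gaussian smoothing (σ = 1.5 px) → automatic binarisation →
8-connected particle detection with a minimum size → intensity
measurement redirected to the raw image.  The rolling ball is
implemented as grey-scale opening with a non-flat ball structuring
element of the stated radius (10 px for punctate channels, 25 px for
filamentous GFAP, at the 102.4 nm/px mapping scale); for radii above
16 px the image is shrunk by a block minimum, the ball rolled on the
coarse grid and the background re-expanded bilinearly, capped by the
image from above.  In the orchestrated pipeline the ball is held at a
constant *physical* size (≈1.02 µm), i.e. ~51 px on the 19.97 nm STED
grid — a 10-px ball at that scale would be 200 nm wide and would carve
away the structures themselves.

**Thresholds.** Punctate channels use the moment-preserving (Tsai)
threshold; GFAP uses Li's minimum-cross-entropy threshold.  Both are
computed on a 256-bin histogram spanning the image min–max range, as the
algorithms are defined for 8-bit data.  The moments rule solves for the
two representative grey levels and mixing fraction that preserve the
first three histogram moments and cuts at the background-fraction
quantile; the Li rule iterates the fixed point
t ← (μ_b − μ_f)/(ln μ_b − ln μ_f) on positivity-shifted bin coordinates
and then polishes the converged cut against the discrete cross-entropy
objective over neighbouring bins, because the continuous fixed point can
sit a bin or two off the discrete minimiser.  Both rules agree with
exhaustive-search implementations within ±1 bin on two-population
histograms (the regime in which thresholding is meaningful).

VGLUT2 is the one channel the protocol thresholds manually.  The
pipeline's deterministic surrogate for that manual step is a robust
noise rule — median + 8·1.4826·MAD of the processed image — which tracks
the operator's intent of keeping every substructure above the noise
floor.  Histogram rules are unreliable here: the moments threshold
follows the bright substructure tail and drops dim boutons, while the Li
iteration is bistable on sparse, high-dynamic-range fields and can
collapse into the background mode.  The same noise floor also bounds
every auto threshold in the pipeline from below, so a channel with no
real structures yields an empty mask instead of binarised noise.

**Hierarchy.** Whole PSDs come from the confocal-resolution PSD95
channel; NCs from the correlative STED channel (minimum particle size
8 px, per the protocol).  The two acquisitions share stage coordinates,
so registration is assumed exact.  Each NC is assigned to the PSD whose
mask holds the plurality of its pixels (mapped through physical
coordinates when grids differ); ties break toward the lower PSD id, and
NCs overlapping no PSD are orphans excluded from per-PSD counts.  PSDs
classify as 0NC/1NC/2NC/3+NC; 0NC PSDs are excluded from NC-fraction
denominators (both denominators are available in the tables).

**Colocalization.** Object-based: a presynaptic or astrocytic structure
is associated with a PSD when its binarised mask overlaps the binarised
PSD mask by ≥ 1 pixel, evaluated on the finer of the two grids
(nearest-neighbour resampling of the coarser).  PSDs then fall into four
categories — PSD only, PSD + astrocyte, synapse (PSD + VGLUT bouton),
tripartite synapse (both) — which partition the population.  The
deliberately generous blur of the confocal PSD mask is what lets
physically apposed but non-overlapping partners register as contacts.

**Spatial statistics.** Per PSD: centre-to-centre distances to the 10
nearest astrocytic puncta (NaN-padded when fewer exist) and the count
within a closed 3 µm radius; per STED field, counts of astro domains
within 200 nm edge–edge of each PSD (overlap → distance 0, else minimum
boundary-pixel distance).  The spatial null rotates the comparison
channel 180° about the frame centre — an involution that preserves every
object-level statistic exactly while destroying spatial association.

**Sizing.** NC geometry is measured as full width at half maximum
(FWHM) along the intensity-weighted principal axes, through the weighted
intensity centre.  Profiles are sampled at ≤ half-pixel spacing with
cubic-spline interpolation (bilinear sampling convolves the profile with
a triangle kernel, adding ≈ px²/6 of variance and biasing a σ = 30 nm
peak by > 5% at the 19.97 nm grid; cubic keeps the worst-case bias under
1.5%).  The peak value is estimated by a least-squares parabola over the
samples within 80% of the maximum — on noisy profiles the raw sample
maximum is an upward-biased order statistic that shrinks the measured
width.  The baseline is the lower of the two profile end values
(configurable).  Only isolated objects are sized: any neighbour centroid
within 400 nm (configurable) skips the record, operationalising the
protocol's restriction to structures that appear alone.

**Mapping.** Laminar ROIs (Rexed scheme I-II … X) are simple polygons in
physical µm; PSDs are assigned by centroid point-in-polygon (boundary
counts as inside; overlapping ROIs are rejected naming the pair).
Per-lamina summaries: whole-field mean raw intensity, PSD density per
100 µm² (unit configurable and written to headers), mean PSD intensity,
median PSD size, mean integrated intensity (mean × pixel count — a
content proxy combining brightness and size).  Aggregation treats the
animal as the statistical unit: hemisection means per animal, then
animal values into group mean ± SEM.  Only the Pearson contingency
chi-squared (Σ(O−E)²/E, expected counts from margins, no continuity
correction) is implemented from formula; other inferential tests are run
on the animal-level tables with standard statistical libraries.

## The synthetic scene generator

The generator produces the ground truth every stage is validated
against.  A scene is: PSDs at a Poisson-drawn count with a minimum
mutual separation (default 0.15 /µm², ≥ 1.2 µm apart, in a 20×20 µm
field with a 0.7 µm margin); per PSD a nanocluster count drawn from
{1: 0.53, 2: 0.31, 3: 0.16} (so 47% of PSDs are 2+NC, the ventral-horn
condition); a VGLUT bouton on 45% of PSDs; an astrocytic nanodomain on
56% of bouton-bearing PSDs (the tripartite fraction) and 15% of the
rest; plus free-floating decoy astro domains at 0.05 /µm².

Objects are anisotropic 2-D Gaussians whose amplitude is a total photon
count.  Size distributions are lognormal around literature medians: NC
axes 92 × 185 nm, VGLUT2 substructures 90 nm, VGLUT1 272 nm, astro
domains 119 nm.  Amplitudes are lognormal around a constant per-class
median (2×10⁴ photons for NCs, σ_log = 0.2) — NC size is conserved while
marker concentration varies, so a fixed photon budget with scatter is
the appropriate model; making photons proportional to footprint area
widens the peak-brightness distribution until auto-thresholds drop
dim-large objects.

**Multi-NC geometry is constrained to keep the truth observable.**  The
mid-point dip between two equal Gaussians separated by d is
2·exp(−d²/8σ²) of the peak, with σ the apparent sigma *along the
separation axis*; components split under thresholding only when that dip
falls below the threshold, which on these fields lands around 0.4–0.5 of
a typical peak.  At confocal resolution (σ ≈ 122 nm) the same pair must
instead stay connected.  Random placement cannot satisfy both, so
multi-NC PSDs use a hub-and-spoke layout: one NC at the centre, siblings
at 260–300 nm with ≥ 110° angular separation, spoke long axes tangential
(±15°) and the hub's long axis steered away from spoke directions.
Presenting the short axis (σ ≈ 52 nm with the 80 nm PSF) along the
hub–spoke line keeps the STED dip below ~0.36 of the peak, while the
confocal bridge stays above ~0.75 — one blob at low resolution, distinct
blobs at high resolution, which is exactly the biological picture the
two-scale analysis presumes.

**Contacts.**  A linked bouton or astro domain is placed against the
half-maximum contour of a randomly chosen NC of its PSD, with an
edge–edge gap drawn uniformly from 0–40 nm (cleft-scale apposition).
Because the binarisation contour of a rendered object tracks roughly its
half-maximum, this guarantees linked partners satisfy the ≥ 1 px overlap
rule once rendered, while decoys colocalize only by chance.

**Rendering.**  Convolution of a Gaussian object with a Gaussian PSF is
closed-form (covariances add), so channels are rendered exactly: each
object's convolved profile is sampled at pixel centres over a 6σ window
and scaled by pixel area, plus a constant background (10 photons/px).
This yields machine-precision oracles for photon conservation
(Σ pixels = background·n_px + Σ amplitudes) and the FWHM composition law
(FWHM_app² = FWHM_obj² + FWHM_PSF²).  Grid presets: widefield mapping
102.4 nm/px with a 320 nm PSF; correlative confocal and STED both at
19.97 nm/px with 250 nm and 80 nm PSFs.  Noise is Poisson shot noise
followed by additive Gaussian read noise (sd 2), clipped to the bit
depth; `psf_fwhm_nm = 0` renders a delta PSF for closed-form checks.
Default amplitudes put single-NC peaks near 290 photons over the 10
photon background at STED sampling (peak SNR ≈ 17).

**What the generator does not emulate** — and therefore what passing
tests do not certify on real data: 3-D structure and optical
sectioning, spectral bleed-through, chromatic offsets or registration
error between the confocal and STED passes, non-Gaussian PSF tails,
spatially varying background and illumination, astrocyte arbor
morphology (GFAP filaments), and the possibility of genuinely
unresolvable NC pairs, which in real tissue are counted as one.  The
recovery results bound algorithmic error, not instrument error.

## Problem sizes and determinism

Fast tests use 20×20 µm fields (~60 PSDs); recovery-style runs use
30×30 µm (~130 PSDs, ~60 synapses) so that a single colocalization flip
moves a fraction by under 2 points, and the reproduction script pools
ten such fields (~600 synapses) for the tripartite percentage.  Every
random draw flows from an explicit integer seed through
`numpy.random.default_rng`; identical (parameters, seed) give
bit-identical scenes, images and tables.  Channel seeds are derived from
the base seed with `SeedSequence`, so channels are independent but
reproducible.

## Known limitations

* The plurality-overlap NC assignment cannot split an NC that straddles
  two PSDs (the original region-restricted counting could count it in
  both); with PSDs ≥ 1.2 µm apart this does not occur in practice.
* Edge–edge distances use boundary-pixel centres, so they are quantised
  to the pixel grid and may differ from subpixel contour distances by up
  to ~one pixel.
* The 180° rotation is a single deterministic null; torus shifts or
  Monte-Carlo repositioning would give a null distribution rather than
  one control value, and are out of scope.
* `aggregate_animals` propagates NaN when a group has a single animal
  (SEM undefined); callers should check `n_animals`.
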