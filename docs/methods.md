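# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `boutonquant`, and what the synthetic generators do and
do not emulate.

## Glutamate-transient quantification

Each pixel trace of a single-bouton movie is low-pass filtered with a
zero-phase second-order Butterworth at 100 Hz (the acquisition runs at
1.6 kHz).  Zero-phase filtering was chosen because a causal filter would
shift peak times and bias the paired-pulse windows; only the cutoff is
dictated by the measurement protocol.  ΔF/F is expressed in percent of the
pixel's mean filtered fluorescence over the 50 ms preceding the first
stimulus, and the per-pixel baseline SD is computed on the same filtered
ΔF/F window, so the 3×SD activity threshold and the signal live on one
scale.  A switch (`threshold_on_filtered=False`) computes both on raw
traces instead; with noise-free input the unfiltered path is exact and is
what ground-truth mask comparisons use.  A tiny absolute floor (10⁻⁹ %) on
the threshold keeps float roundoff of an exactly-constant movie from
registering as activity.

Active-pixel statistics are computed over the whole ROI; the bouton mask
only normalizes the active fraction, because release is read out at the
membrane and slightly beyond it.  Frames with no active pixel report
cumulative 0 (a sum over the empty set) but mean and maximal amplitudes as
missing (NaN), not zero — zeros would bias trace averages downward.
Per-stimulus peak windows are [stimulus, stimulus + 50 ms), closing early
at the next stimulus; 50 ms mirrors the interstimulus interval.  The decay
fit A·e^(−(t−t_peak)/τ) + c runs from the cumulative peak after the chosen
stimulus (default: the last) to the end of the recording; the additive
offset c absorbs residual baseline drift, and fits with non-positive or
divergent τ, or vanishing amplitude, raise instead of returning a number.

Units are ms, %, and μm² throughout; cumulative amplitude is %·pixel with
the pixel size recorded so %·μm² is derivable.

## Bouton-movie generator

The forward model: discrete release sites inside a circular 13×13-pixel
bouton (0.2 μm/pixel); at each stimulus each site releases independently
with `site_release_prob`; glutamate spreads as an in-plane isotropic
Gaussian (σ = 0.25 μm default) truncated at 3σ and follows a linear rise
(1 ms) / monoexponential decay (15 ms) time course; the saturating sensor
maps concentration to ΔF/F = dff_max·[Glu]/([Glu]+Kd) with Kd = 600 μM;
fluorescence is baseline·(1 + ΔF/F/100)·bleach(t) plus Gaussian noise.
Bleaching is a single multiplicative exponential (off by default),
motivated by the ~50 % monotone decline seen in longitudinal recordings.

Per-site release probabilities and quantal cleft concentrations at mossy
fiber boutons are not published; the defaults (p = 0.5, 300 μM per
quantum) are placeholders chosen to put single-pulse responses in the
lower part of the sensor's working range.  The 3σ truncation makes the
"active footprint" a well-defined pixel set, so noise-free mask recovery
can be asserted exactly; because the temporal kernel never reaches zero,
the true active mask at stimulus j is the union of footprints of all sites
that released at any stimulus ≤ j.

Two contrast experiments use non-default configurations, fixed once:

* *Recruitment signature* (area and cumulative rise, mean amplitude flat
  when sites double): a 21×21 ROI with σ = 0.15 μm keeps footprints mostly
  disjoint; with heavily overlapping footprints, doubling sites raises the
  summed concentration rather than the covered area, which is summation,
  not recruitment.
* *Homogenization* (many synchronous sites give smaller entropy and
  non-triviality excursions than one dominant site): σ = 0.5 μm and
  [Glu] ≫ Kd, so eight sites saturate the whole bouton into a flat,
  noise-dominated plateau while one site produces a strong oriented
  gradient.  With compact footprints the window-coverage effect dominates
  and the contrast inverts; widespread saturating release is the regime in
  which homogenization is observable.

## Pattern entropy and non-triviality

The committed realization is the 2×2 ordinal-pattern construction: every
2×2 window (stride 1) is mapped to the rank permutation of its four values
(ties broken by raster position, so a constant field gives the identity
pattern), a 24-letter alphabet.  H is the Shannon entropy of the pattern
frequencies normalized by log 24; the disequilibrium Q_JS is the
Jensen–Shannon divergence to the uniform distribution, normalized by its
maximum (attained at a point mass), and C = H·Q_JS.  Both statistics are
rank-based and therefore exactly invariant under adding constants or
positive rescaling.  Frames are analyzed on the bounding box of the bouton
mask dilated by 2 pixels; windows touching pixels outside the region are
excluded.  Amplitudes compare the 50-ms pre-stimulus baseline mean with
the value at the frame of peak cumulative response, signed so that the
physiological direction (entropy falls, non-triviality rises on release)
is positive.  No numerical identity with any particular published
implementation is claimed; the realization reproduces all the qualitative
limits (ordered field → H = C = 0; i.i.d. noise → H → 1, C → 0; oriented
features at intermediate H → larger C).

## STED coupling distances

The PSF is a radial 2D Lorentzian 1/(1 + (2r/FWHM)²) with 40-nm FWHM at
20-nm pixels, truncated at 10×FWHM and renormalized to unit sum — the
heavy tails must be bounded for finite convolution.  Richardson–Lucy
deconvolution (default 30 iterations; the count is conventional, chosen
where the two-spot recovery test passes) is implemented with
replicate-edge padded FFT convolutions, which makes a uniform field a
fixed point and conserves total intensity within 1 %; the iteration is
verified against scikit-image's implementation on interior pixels.

Maxima are retrieved by topographic prominence: pixels are flooded in
order of decreasing intensity with union-find merging; when two summit
components meet at level v the lower summit's prominence is fixed at
(height − v), surviving summits are referenced to the image minimum, and
connected equal-valued summit plateaus are reported at their centroid.
Only maxima with prominence strictly above the threshold are returned.
The threshold is scale-dependent (the conventional ">20" belongs to a
particular software's intensity scale); synthetic fields rendered at
~1000-count spot amplitudes use prominence 100, which cleanly separates
real spots from deconvolution-amplified noise speckle.

Triad gating replaces manual synapse selection: candidate Cav–Munc pairs
within 250 nm are matched greedily one-to-one by ascending distance, and a
pair is accepted only if both members lie within 200 nm of a common Homer
spot.  The pair radius sits beyond the largest distances observed at these
synapses (~200 nm), the Homer radius at the synapse scale; both are
mandatory in reports.  The distance is read along the straight line
through both maxima (extended 10 pixels beyond each) with nearest-pixel
sampling — the grid-based line-profile procedure — as
|s_cav − s_munc|·pixel size; bilinear sampling is available for
sensitivity analysis.  Because nearest-pixel reads of an oblique line can
repeat one pixel value at adjacent samples, the profile peak is taken at
the centre of the tied plateau rather than its first sample — a first-
occurrence argmax systematically drags both peaks toward the profile
start and leaves a separation-dependent shrinkage of ≈ 1–2 nm.  With the
centred tie-break, quantization error is bounded by pixel/√2 per endpoint
and near mean-zero: the recovered group mean is unbiased to ≈ 0.2 nm at
20-nm pixels (504 synapses).

The STED generator draws separations from a named family (point mass,
uniform, or normal truncated at zero; default μ = 64.6 nm, σ = 35 nm —
σ chosen so the per-synapse spread matches an SEM of ~1.4 nm at n ≈ 580
and ~95 % of distances fall below 120 nm), orients each pair uniformly in
[0, 2π), and displaces the Homer spot 90 nm from the pair midpoint
perpendicular to the pair axis (trans-synaptic geometry).  Spots are
rendered by evaluating the Lorentzian analytically at pixel centers around
the continuous source position, so sub-pixel ground truth is preserved;
Poisson shot noise, Gaussian read noise and per-channel distractor spots
complete the image model.  The recovery study (`boutonquant.studies`)
matches each measured synapse back to its generating triad, separating
measurement error from sampling error; the shifted-condition study reuses
the same seed, a paired (common-random-numbers) design that isolates the
10-nm generative shift from sampling noise of the separations.  The
Mann–Whitney power check at n = 500/group runs on separation draws rather
than on 100 repetitions of the full image pipeline; one pipeline
repetition per condition establishes that measurement adds ≈ 9 nm RMS
per-synapse error and negligible bias, which leaves the power essentially
that of the underlying distributions.

## EM morphometry

All inputs are geometries in nm (the package does not segment
micrographs).  Complexity is perimeter/area of the largest presynaptic
profile; volume is Σ section polygon area × 70 nm.  AZ identity across
sections is explicit (az_id) rather than inferred from overlap, keeping
the statistic deterministic; per-AZ area is Σ trace length × thickness.
Vesicle z is the section mid-plane: within-section z offsets are
unknowable from 2D segmentation, and the resulting slight MNND
underestimate is reproduced, not corrected.  The dispersion estimator —
"distance from each vesicle to all others, normalized by stack volume" —
is implemented as the mean over unordered pairs divided by the
reconstructed volume (nm/μm³); sum and per-vesicle-mean variants exist
behind `pair_statistic` because the units admit any of them, and the mean
is used in all reports.  Docked/tethered cutoffs are configuration values:
gap ≤ 2 nm to the nearest same-section AZ trace (membrane contact) for
docked, center ≤ 60 nm for tethered; docked + tethered approximates the
readily releasable pool.  MNND is the mean over vesicles of the
within-section 2D nearest-neighbor distance, pooled across sections
(count-weighted); sections with fewer than two vesicles contribute
nothing.

The generator stacks one rough-boundary profile (low-order harmonic radial
modulation, rescaled to the requested area exactly) across sections, puts
AZ arcs on the membrane over contiguous sections, and places three vesicle
populations: docked (center at one radius from an AZ trace, gap 0),
tethered (center within the 60-nm shell), and free vesicles from a uniform
or Thomas (parent–offspring) process, all under a 3D hard-core constraint
(40 nm) with bounded rejection.  Free vesicles keep a margin beyond the
tether cutoff from every AZ trace so the docked/tethered ground truth is
exactly what the classifier should recover — a deliberate idealization;
in real micrographs the populations grade into each other.  Mitochondria
are concentric scaled copies of the profile occupying an exact volume
fraction.  The dispersion-ordering study compares the uniform process with
a single tight depot (parent intensity 1, offspring σ = 80 nm): with
several depots the inter-depot distances — a property of depot placement,
not of clustering — can exceed the uniform mean and confound the ordering.

## Group statistics

The D'Agostino–Pearson omnibus test needs n ≥ 8; smaller samples are
routed directly to Mann–Whitney (conservative, and recorded).  The Welch
upgrade is gated by a two-sided F test of variance equality at α = 0.05 —
the gate test itself is a design choice, as the convention only says
"when variances differ significantly".  Mann–Whitney p-values are exact
for min(n) ≤ 8 without ties, normal-approximated with tie correction
otherwise; calibration of the full selection procedure is checked on
Gaussian nulls (rejection rate 0.05 ± 0.015 at n = 20/group over 2,000
seeds).  Both pooled per-observation and per-animal summaries are always
emitted; no multiple-testing correction is applied, and nested
(mixed-effects) modeling is out of scope — the per-animal means are the
pragmatic guard against pseudoreplication.

## Problem sizes and limitations

The acceptance studies run at desk scale: 500 synapses per condition for
coupling recovery (≈ 42 fields of 256×256 px with 12 triads each), 100
seeds for τ recovery and dispersion ordering, 2,000 seeds for test
calibration, ≥ 10⁵ pixel-frames for the false-positive rate.  The
false-positive check constructs the ΔF/F field with its exact generating
SD, isolating the thresholding rule itself; estimating the SD from a
finite 50-ms baseline adds a small positive bias to the exceedance rate
(a t-tail rather than a normal tail) that is a property of any finite
baseline, not of the implementation.

What passing tests do not show: the generators contain no motion, no
focal drift, no autofluorescence background, no chromatic offset between
STED channels, no section-alignment artifacts, and no segmentation error —
inputs to the EM module are perfect geometries.  Results on real data
inherit all of those error sources; the synthetic studies validate the
estimators, not the acquisition.
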