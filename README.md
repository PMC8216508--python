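# boutonquant

Quantification pipelines for presynaptic potentiation at large hippocampal
mossy fiber boutons (hMFBs) — the giant terminals that dentate granule cell
axons form on CA3 pyramidal neurons.  When these synapses potentiate (for
example after cAMP elevation by forskolin), the change can live in release
probability, in the number of active release sites, in the nanoscale
coupling between calcium channels and release machinery, or in vesicle
organization.  Telling these apart requires quantitative readouts from three
very different kinds of microscopy; `boutonquant` implements all of them as
a tested Python library, together with synthetic-data generators that stand
in for the microscopes so that every statistic can be validated against a
known ground truth.

## What it computes

**Glutamate-sensor transients** (`boutonquant.iglu_transients`).
Time-lapse movies of a membrane-bound, low-affinity glutamate sensor
(Kd = 600 μM) recorded at 1.6 kHz are converted to ΔF/F in percent of each
pixel's mean baseline fluorescence F (50-ms pre-stimulus window, 100-Hz
low-pass).  A pixel is *active* when ΔF/F > 3 × its baseline SD.  Per frame
the module tracks the active area A(t), the cumulative amplitude
Σ ΔF/F over active pixels, and the mean and maximal amplitudes; per
stimulus it reports peaks, paired-pulse ratios (PPR = peak₂/peak₁), the
monoexponential decay constant τ of the cumulative transient
(A·e^(−t/τ) + c), and the virtual bouton diameter d = 2√(A/π).

**2D pattern statistics** (`boutonquant.pattern_stats`).
The spatial ΔF/F field is summarised by its ordinal-pattern distribution
(rank order of each 2×2 window, 24 symbols): normalized entropy
H = −Σp log p / log 24 measures homogeneity, and non-triviality
C = H · Q_JS (Q_JS the normalized Jensen–Shannon distance to the uniform
distribution) measures anisotropy.  Evoked release lowers H and raises C;
widespread synchronous release attenuates both excursions.

**STED coupling distances** (`boutonquant.sted_coupling`).
Three-channel super-resolution images (Cav2.1 / Munc13-1 / Homer1, 20-nm
pixels) are deconvolved (Richardson–Lucy, 2D Lorentzian PSF, 40-nm FWHM),
cluster maxima are retrieved by topographic prominence, Cav–Munc pairs are
gated on juxtaposition to a Homer spot, and the coupling distance is the
peak-to-peak separation along a 1-pixel line profile through both maxima —
aggregated into 20-nm histograms and per-condition / per-animal summaries.

**EM morphometry** (`boutonquant.em_morphometry`).
From serial-section reconstructions (70-nm sections; polygons, AZ traces,
vesicle centers): bouton complexity (perimeter/area), reconstructed volume,
AZ density and area, vesicle density, volume-normalized pairwise dispersion
(mean 3D inter-vesicle distance / volume, nm/μm³), 2D mean nearest-neighbor
distance, docked (membrane contact) and tethered (center ≤ 60 nm) vesicle
densities — docked + tethered approximates the readily releasable pool —
and the mitochondrial volume fraction.

**Group statistics** (`boutonquant.group_stats`).
The comparison logic of the quantitative-microscopy literature: a
D'Agostino–Pearson normality screen routes data to an unpaired t test
(Welch under unequal variance) or a Mann–Whitney U test (exact p for small
tie-free samples); distributions are compared by two-sample
Kolmogorov–Smirnov; stars at p < 0.05 / 0.01 / 0.001 / 0.0001.

**Synthetic data** (`boutonquant.synthetic_data`).
Seeded generators for all three modalities — saturating-sensor bouton
movies with discrete stochastic release sites, STED fields of Lorentzian-
blurred synapse triads, and serial-section bouton geometries with
clustered or uniform vesicle point processes — each returning its exact
ground truth.

## Worked example

```bash
python examples/coupling_distance.py
```

```
recovered 10 synapses from 10 generated triads
measured (nm): [0.0, 30.0, 30.0, 40.0, 40.0, 60.0, 80.0, 80.0, 100.0, 140.0]
true     (nm): [2.0, 27.0, 36.0, 37.0, 57.0, 63.0, 77.0, 94.0, 117.0, 124.0]

mean +/- SEM: 60.0 +/- 12.9 nm (n = 10)
20-nm histogram counts: [1, 2, 2, 1, 2, 1, 1]
```

One simulated field (truncated-normal separations, μ = 64.6 nm) runs
through deconvolution, maxima detection, triad gating and line-profile
measurement; the per-synapse distances track the generating truth and the
mean sits in the ~65-nm loose-coupling regime typical of mossy fiber
boutons.  The other examples (`transient_analysis.py`, `pattern_entropy.py`,
`em_morphometry.py`, `group_comparison.py`) do the same for the remaining
pipelines.

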