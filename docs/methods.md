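# Methods

This note documents the model implemented by `icao2sat`, the reasoning
behind its defaults, what the synthetic phantoms do and do not emulate,
and the method's known limitations.

## Signal model

BOLD contrast makes the effective transverse relaxation rate R₂\* (ms⁻¹)
increase with local deoxyhaemoglobin concentration. A dynamic
gradient-echo acquisition therefore yields, per tumour voxel, a time
series whose slow fluctuations reflect oxygenation cycles. We model the
masked data matrix **X** (time × voxels, per-voxel temporal mean removed)
as a linear superposition of a small number of sources plus broadband
noise, and attribute each source to one of:

* **systemic** — driven by fluctuations of arterial oxygen saturation
  delivered by the feeding vasculature. The physiological sign is
  negative (O₂sat up ⇒ deoxyhaemoglobin down ⇒ R₂\* down), but no stage
  of the pipeline depends on the sign: component order and sign out of
  ICA are arbitrary, so all tests are two-sided or magnitude-based.
* **tumour-specific** — generated inside the tumour (vasomotion,
  transient vascular remodelling, interstitial pressure), uncorrelated
  with the systemic trace, typically spatially clustered and spectrally
  narrow at or below 10⁻³ Hz.
* **noise** — everything else.

No temporal lag between the O₂sat trace and the tumour response is
modelled: murine circulation times are well below the 3.8 s frame
interval.

### R₂\* estimation

When multi-echo gradient-echo magnitudes are supplied instead of R₂\*
maps, R₂\* is fitted per voxel by ordinary least squares of −ln S(TE)
against echo time — the closed-form estimator for mono-exponential decay.
Single-echo dynamic data may be supplied directly as an R₂\*-weighted
proxy series; all downstream stages are invariant to a per-voxel affine
rescaling, so the proxy supports the same decomposition.

### PCA and eigenvector selection

**X** is decomposed by SVD (exact; `min(n_frames, n_voxels)` eigenvalues
in sample-variance units, so they sum to the total per-voxel temporal
variance). Retained are

1. every eigenvector up to the **shoulder** of the ranked eigenvalue
   curve, defined as the point of maximum perpendicular distance from the
   chord joining the first and last points of the normalised
   (rank, log₁₀ variance-fraction) curve — the standard knee heuristic,
   with ties toward the smaller index, the distance profile exposed for
   auditing, and numerically-zero eigenvalues (the mean-removal rank
   deficiency) excluded from the curve because their logarithms would
   otherwise dominate the normalisation; and
2. every post-shoulder eigenvector whose time-course has a **dominant
   spectral peak**: maximum one-sided periodogram power (zero bin
   excluded) at least `peak_ratio` times the median of the remaining
   bins.

`peak_ratio` defaults to 15. The calibration is analytic: for a white
time-course of n ≈ 950 frames the periodogram ordinates are approximately
i.i.d. exponential, the maximum of ~475 of them lands near ln(475) ≈ 6.2
means while the median sits at ln 2 ≈ 0.69, so chance alone produces a
max/median ratio near 9 — a threshold of 10 would flag pure noise ~40% of
the time, while 15 flags it ~1.5% of the time (both confirmed by
simulation). The ratio is configurable; raising it can only shrink the
selection (monotonicity is tested).

### Spatial ICA

The rank-reduced data are whitened along the voxel dimension through
their SVD and unmixed by FastICA (log-cosh contrast, symmetric updates,
`tol = 1e-6`, `max_iter = 1000`, fixed seed). Voxels are samples;
the rows of **S** are the independent spatial maps (≈ zero-mean, unit
variance) and **M = X·S⁺** holds the component time-courses, which makes
**M·S** equal the rank-k data to machine precision by construction.

Because the selection rule deliberately retains noise eigenvectors, part
of the whitened subspace is close to Gaussian and has *no* preferred
rotation: the global FastICA convergence criterion is then generally not
met within any iteration budget, even though the genuinely non-Gaussian
source directions stabilise early. The implementation follows standard
BOLD-ICA practice and uses the final iterate, reporting
`converged=False` and a warning; `on_nonconvergence="raise"` turns this
into an error for callers who require strict convergence. Component
order (descending explained variance) and sign (largest-magnitude map
value positive) are canonicalised so runs are bit-reproducible under a
fixed seed.

### Classification

Per component, against the O₂sat trace linearly interpolated to frame
mid-points:

| evidence | rule | default |
|---|---|---|
| systemic | Pearson two-sided p (t transform, n−2 df) | p < 0.01 |
| tumour-specific (i) | dominant spectral peak of the time-course | `peak_ratio` = 15 |
| tumour-specific (ii) | cluster of face-connected voxels at \|z\| ≥ 2.2 **and** distinctive time-course | ≥ 5 voxels; lag-1 autocorrelation ≥ 0.3 |

"Distinctiveness" is operationalised as the lag-1 autocorrelation: a slow
oscillation sampled at 3.8 s has r₁ ≈ cos(2πfΔt) ≈ 1, white noise has
r₁ ≈ 0 with s.e. ≈ 1/√n ≈ 0.03, so 0.3 separates the two by ~10 s.e.
Clusters use 6-neighbour (face) connectivity across slices —
slow oxygenation structures span slices — configurable to 18/26.

No multiple-testing correction is applied at either level; thresholds act
on raw p-values. **Consequence at long acquisitions:** with n = 947
frames, p < 0.01 corresponds to |r| > 0.084. The time-course of any weak
component inherits leakage from much stronger components (leakage ≈
unmixing error × amplitude ratio), so when one source dominates the
variance, many noise components end up component-labelled systemic. This
inflates the per-class *component counts* but not the voxel maps: the
voxel-level thresholding below removes the leakage.

### Reconstruction and voxel thresholding

Class fields are rebuilt by summing **M** columns × **S** rows over each
class; the three class fields sum to **M·S** exactly. Voxel rules:

* systemic map: X̂ˢʸˢ time-course vs O₂sat, two-sided p < 0.01;
* tumour-specific map: X̂ᵗ⁻ˢᵖ time-course vs O₂sat, p > 0.05
  (no evidence of systemic coupling);
* voxels of X̂ᵗ⁻ˢᵖ in the indeterminate band 0.01 ≤ p ≤ 0.05 join
  neither map and are counted in the run report.

The maps may overlap: a voxel can carry both signals.

**Amplitude gate.** Correlation is scale-free: an arbitrarily small
spill-over of a component into a voxel reproduces the component's
correlation (or lack of it) exactly, so the p-rules alone would label
essentially every voxel. A voxel therefore enters a class map only if the
class field's temporal s.d. there is at least `amplitude_gate` (default
0.5 — "the class signal reaches at least half the noise floor") times
the voxel's noise s.d. The noise reference is the larger of (a) the
per-voxel residual s.d. after the rank reduction, and (b) a global robust
estimate from the eigenvalue spectrum, σ̂² = median(λ)·m/n_voxels — the
median of the noise bulk is insensitive to the few signal eigenvalues,
and reference (b) matters exactly when the selection has swallowed most
of the spectrum (signal-free data), leaving a misleadingly small
residual. A relative floor of `leak_floor` (default 0.01) × the largest
class s.d. additionally suppresses solver-tolerance leakage in noiseless
data. On signal-free phantoms the combined gate holds false-positive
voxels below 2% per class.

### Frequency analysis

Per-voxel spectra are |DFT|²/n of the mean-removed time-course, one-sided
with interior bins doubled, so the per-voxel spectral sum equals n × the
(population) time-domain variance (Parseval; asserted in tests). No
window or detrending is applied by default. Voxel spectra are averaged
arithmetically; cohorts are summarised per bin by mean and sample s.d.;
the dominant frequency is the maximum-power bin, ties toward the lower
frequency. Bin width is 1/(n·Δt) ≈ 2.78 × 10⁻⁴ Hz for the default
947-frame, 3.8 s acquisition; Nyquist is 1/(2Δt) ≈ 0.13 Hz.

### Statistics

Cohorts in this setting are tiny (five animals per group), where normal
approximations to rank tests are invalid. The Wilcoxon matched-pairs test
is exact for n ≤ 20 (distribution of the positive-rank sum by
convolution, equivalent to full 2ⁿ enumeration — verified against direct
enumeration in tests), Mann-Whitney U is exact for pooled n ≤ 12 by
labeling enumeration, Spearman's ρ is exact for n ≤ 8 by permutation
enumeration. Two-sided exact p-values are 2 × min(lower tail, upper
tail), each tail including the observed point, capped at 1 — conventions
differ between packages, so this is stated explicitly. Zero differences
are dropped (with a warning); tied magnitudes receive mid-ranks.

Worth noting: the minimum attainable two-sided exact p at n = 5 is
2/2⁵ = 0.0625, so no five-pair comparison can reach p < 0.05 — the
"4 out of 5" configuration gives exactly p = 0.125.

### Histology quantification

Coverage is strictly pixel-wise: fraction of ROI pixels above a
background threshold per fluorescence channel, and vessel maturity as the
percentage of CD31-positive pixels colocalised with α-SMA. Background
thresholds must be supplied; Otsu's method is offered as an explicit,
logged fallback. No vessel segmentation, stain deconvolution or
histology-to-MRI registration is attempted.

## The phantom: what it emulates, and what it does not

`phantom.generate_phantom` emulates the study acquisition: a 32 × 32 × 5
grid, 947 frames at 3.8 s (~60 min), an ellipsoidal tumour of ~1750
voxels, baseline R₂\* 0.12 ms⁻¹, and a 1 Hz O₂sat trace (baseline 95%,
slow sinusoidal excursion ±3%, AR(1) noise of 0.2% s.d.) linearly
interpolated to frame mid-points. Injected sources:

* a systemic fluctuation −gain·(O₂sat−mean), gain 0.004 ms⁻¹ per %, in a
  **peripheral shell** (all mask voxels beyond 9 in-plane voxels from the
  tumour axis; 564 voxels, 32%) — systemically driven fluctuations
  concentrate at the rim, where the feeding vasculature enters;
* two ellipsoidal tumour-specific **clusters** (141 voxels each) in the
  core, sinusoids of amplitude 0.012 ms⁻¹ with random phase;
* white Gaussian noise, s.d. 0.004 ms⁻¹, giving both signal classes an
  amplitude SNR of 3.

Two geometry choices are deliberate validation design, not physiology:

1. **Window-harmonic frequencies.** Defaults are exact harmonics of the
   acquisition window (2/T ≈ 5.56 × 10⁻⁴ Hz systemic, 3/T ≈ 8.34 × 10⁻⁴
   Hz tumour-specific; both below the 10⁻³ Hz cycling-hypoxia bound). Two
   generic sub-millihertz sinusoids are *not* orthogonal over a finite
   hour: spectral leakage produces |r| up to ~0.10 between them, above
   the p = 0.05 significance radius at n = 947, which would make the
   ground-truth class of a cluster voxel genuinely ambiguous. A
   validation phantom must have unambiguous truth, hence commensurate
   frequencies.
2. **Disjoint source supports.** Overlapping supports make the spatial
   sources *correlated*, which orthogonal-whitening ICA cannot separate
   exactly; the mixed-in systemic leakage then flips the cluster
   component's label. Defaults keep the shell and clusters disjoint;
   overlap remains available through the configuration and the
   voxel-thresholding stage is verified to place shared voxels in both
   maps when given a separated decomposition.

Not emulated: Rician magnitude noise (Gaussian suffices for pipeline
validation), physiological lag, drifting oscillator phase, scanner drift,
motion, perfusion mechanisms. Passing the phantom tests therefore
demonstrates correct *pipeline mechanics and statistical calibration*,
not performance on real tumours, where source spectra overlap, amplitudes
vary within a class, and sources need not be spatially disjoint.

All randomness flows from a single seed through separate child streams
for the O₂sat trace and the volume, so the standalone trace generator and
the full phantom produce the identical trace.

## Numerical choices

* Sample (n−1) standard deviations throughout, matching the statistics
  module; spectra use the population convention internally where Parseval
  requires it.
* All grids are (time, z, y, x), 0-based; NIfTI I/O transposes to the
  on-disk (x, y, z, t) order and stores the frame interval in the time
  zoom.
* The shoulder, degenerate inputs (constant data, constant maps, all-zero
  spectra, zero-variance correlations) and dropped zero differences are
  flagged rather than silently handled; every threshold and seed of a run
  is echoed verbatim in the JSON report.
* FastICA tolerance 1e-6: for separable sources the extra iterations
  beyond 1e-4 are nearly free and reduce inter-component leakage in
  noiseless data from ~1% to ~0.03% of the class amplitude, well under
  the `leak_floor` gate.

## Limitations

* The component-level p < 0.01 rule is brittle at long acquisitions
  (|r| > 0.084 suffices at n = 947); component counts should be read
  together with the voxel maps.
* Spatially overlapping sources are separated only approximately
  (correlated spatial sources violate the ICA model); the voxel maps may
  then misattribute shared voxels.
* R₂\* is an indirect oxygenation readout; its absolute value does not
  reliably predict oxygen tension, and changes in blood volume, pH or
  haematocrit confound it.
* The 3.8 s sampling folds any faster oscillation into the sub-Nyquist
  range (an aliasing guard on integer down-sampling is tested, but real
  high-frequency physiology cannot be recovered).
* No multiple-testing control, by design parity with the analysis the
  package implements; prevalences are therefore slightly liberal.
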