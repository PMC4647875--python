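# icao2sat

Decomposition of spontaneous tumour oxygenation fluctuations measured by
BOLD MRI into **systemic** and **tumour-specific** sources, using spatial
independent component analysis constrained by a concurrently recorded
pulse-oximetry trace.

## The problem

Solid tumours undergo *cycling hypoxia*: slow (< 10⁻³ Hz) oscillations of
oxygen tension followed by reoxygenation, with major consequences for
radio- and chemotherapy. Dynamic gradient-echo MRI tracks these cycles
through the effective transverse relaxation rate R₂\* = 1/T₂\*, which
rises with the local concentration of paramagnetic deoxyhaemoglobin.
A voxel's R₂\* time-course, however, mixes oscillations that originate
*within* the tumour (vasomotion, vascular remodelling, interstitial
pressure) with oscillations of the *systemic* arterial oxygen saturation
(O₂sat) delivered to it. This package separates the two, given:

* a 4D voxel-wise R₂\* series over a tumour mask (e.g. ~60 min at 3.8 s
  per frame), and
* the simultaneous systemic O₂sat trace from pulse oximetry.

## The model

The masked series is arranged as a matrix **X** (time × voxels) and
decomposed in three steps:

1. **PCA** of the mean-removed time-courses. Eigenvectors up to the
   "shoulder" (knee) of the ranked eigenvalue curve are kept, plus any
   later eigenvector whose time-course shows a dominant spectral peak.
2. **Spatial ICA** (FastICA, log-cosh contrast) of the rank-reduced data:
   **X ≈ M·S**, where the columns of **M** are component time-courses and
   the rows of **S** are maximally independent spatial maps.
3. **Classification and reconstruction.** A component is *systemic* when
   its time-course correlates with the O₂sat trace (Pearson, two-sided
   p < 0.01); otherwise *tumour-specific* when its spectrum has a dominant
   peak, or its |z| ≥ 2.2 map contains a cluster of ≥ 5 face-connected
   voxels together with a non-noise-like time-course; otherwise *noise*.
   Summing M·S over each class rebuilds class-wise R₂\* fields X̂ˢʸˢ and
   X̂ᵗ⁻ˢᵖ; voxels with p < 0.01 against O₂sat on X̂ˢʸˢ are systemically
   oscillating, voxels with p > 0.05 on X̂ᵗ⁻ˢᵖ are tumour-specific (a
   voxel may be both), subject to an amplitude gate that excludes voxels
   where a class field is below the noise floor.

Frequency analysis (voxel-average power spectra, cohort mean ± s.d.,
dominant frequency by peak height), exact small-sample nonparametric
statistics (Wilcoxon matched-pairs by full 2ⁿ enumeration, Mann-Whitney U,
Spearman's ρ) and pixel-wise histology coverage quantification round out
the toolkit. A synthetic-data module generates seeded phantoms with
ground-truth voxel labels for validation.

## Worked example

```python
from icao2sat import PhantomConfig, analyse, generate_phantom

data = generate_phantom(PhantomConfig(seed=0))   # 32x32x5, 947 frames @ 3.8 s
result = analyse(data.series, data.o2sat)
print(result.report)
```

prints (abridged):

```
eigenvectors selected : 27 of 947
component classes     : {'systemic': 24, 'tumour_specific': 2, 'noise': 1}
systemic voxels       : 32.3% of tumour
tumour-specific voxels: 16.1% of tumour
dominant frequencies  : systemic 5.56e-04 Hz, tumour_specific 8.34e-04 Hz
mean fluctuation s.d. : systemic 0.0085 ms^-1, tumour-specific 0.0085 ms^-1
```

The phantom injects a systemic oscillation at 5.56 × 10⁻⁴ Hz into a
peripheral shell (32% of the tumour) and two clustered tumour-specific
oscillators at 8.34 × 10⁻⁴ Hz (16%): the pipeline recovers both voxel
populations and both dominant frequencies exactly (1 bin ≈ 2.78 × 10⁻⁴
Hz). Both frequencies sit below the 10⁻³ Hz (3.6 cycles h⁻¹) range
characteristic of cycling hypoxia. Note that the per-*component* systemic
count is inflated by weak components inheriting time-course leakage from
the dominant systemic source — the voxel-level maps, which are the
scientific output, are unaffected (see `docs/methods.md`).

The same pipeline runs from the shell:

```bash
icao2sat simulate --seed 0 --outdir phantom/
icao2sat run --series phantom/r2star.nii.gz --mask phantom/mask.nii.gz \
             --o2sat phantom/o2sat.csv --outdir results/
```

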