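# tumorvasc

Monitoring how antiangiogenic therapy reshapes a tumor's vasculature and
oxygen supply requires two complementary in-vivo readouts: raster-scan
**optoacoustic (OA) angiography**, which images the vessel network itself
through hemoglobin's optical absorption, and **diffuse optical
spectroscopy (DOS)**, which recovers blood oxygen saturation (StO2) and
hemoglobin content from multi-distance reflectance spectra. `tumorvasc`
implements the full analysis chain behind such a study — reconstruction,
vascular morphometry, spectral inversion, hypoxic-fraction quantification
and longitudinal statistics — together with synthetic-data generators that
replace animal data, so every stage is validated by recovering known
ground truth. It is aimed at researchers developing or benchmarking
preclinical optical/optoacoustic imaging pipelines.

## What is implemented

* **`synthkit`** — vascular tube phantoms, raw OA raster scans (bipolar
  band-limited pulses, 1/r spreading, virtual point detector, per-B-scan
  motion, noise), two-distance DOS spectra, stained-section images and
  two-group longitudinal cohorts; all seeded, all with recorded truth.
* **`oarecon`** — zero-phase 7–100 MHz bandpass, per-B-scan f–k (Stolt)
  migration `P(kx, ω) → q(x, z)` with `ω = c·√(kx²+kz²)`, depth alignment
  of adjacent B-scans (motion correction), an orthogonal-plane second
  pass, Hilbert envelopes, split-aperture sound-speed autofocus, and the
  surface-fluence/ANSI safety arithmetic.
* **`vesselquant`** — 3D CLAHE, multiscale Hessian (Frangi) vesselness
  over 40–140 µm diameters (σ = d/2√2), series-wide reference
  thresholds, binarization with component cleanup, volumetric vessel
  fraction in a VOI, skeleton metrics, and projected vessel area from
  maximum-intensity projections.
* **`dosrecon`** — hemoglobin absorption + power-law scattering +
  extrapolated-boundary diffusion reflectance at 1.75/3.5 mm separations;
  inversion by a trained feed-forward network and by a multi-start
  least-squares oracle, recovering StO2, tHb, HbO2, HHb.
* **`hypoxia`** — control-derived intensity thresholds and relative
  hypoxic fraction (RHF) with necrosis exclusion.
* **`cohortstats`** — caliper volume V = a·b²/2, baseline normalization,
  Shapiro–Wilk, **exact** Wilcoxon signed-rank and Mann–Whitney tests by
  enumeration at cohort sizes, paired/Welch t-tests, Pearson correlation,
  summary tables, microvessel-density normalization.
* **`pipeline` / `analysis/`** — an end-to-end study driver
  (`run_study`) reproducible from a single YAML config, and numbered
  analysis scripts that walk the full study.

See `docs/methods.md` for the models, their assumptions and limits.

## Worked example

```python
import numpy as np
from tumorvasc import synthkit, oarecon, dosrecon, cohortstats

# image a vessel phantom and recover the sound speed
phantom = synthkit.parallel_tube_phantom(3, seed=7, diameter_um=40.0,
                                         depth_range_mm=(0.45, 1.0))
cfg = synthkit.ScanConfig(sound_speed_true=1505.0, n_time_samples=384)
raw = synthkit.simulate_oa_scan(phantom, cfg)
volume = oarecon.reconstruct_volume(raw)
print(volume.sound_speed_used)          # 1504.6  (true: 1505 m/s)

# invert a noisy reflectance spectrum
params = dosrecon.TissueParams(sto2=0.65, thb=60.0, scatter_amp=1.2,
                               scatter_power=1.2)
spec = synthkit.simulate_dos_spectrum(params, noise_sd=0.01, seed=1)
rec = dosrecon.lsq_invert(spec)
print(round(rec.sto2, 3), round(rec.thb, 1))   # 0.651 59.6  (true: 0.65, 60)

# the canonical exact small-sample p-values
x = np.array([2., 3., 4., 5., 6., 7.])
print(cohortstats.wilcoxon_signed_rank(x, np.zeros(6)).p_value)  # 0.03125
print(cohortstats.mann_whitney(x, x + 10).p_value)               # 0.0021645
```

The laser-safety check from the system's printed parameters:

```bash
tumorvasc fluence
# fluence: 1.263 mJ/cm^2 (within the 20 mJ/cm^2 limit)
```

A full synthetic study (cohort, imaging exemplar, DOS inversion for every
animal/timepoint, endpoint hypoxia sections, statistics tables):

```bash
tumorvasc run --out results/study --seed 0
```

or step by step through `analysis/01_simulate_study.py` …
`analysis/05_cohort_statistics.py`.

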