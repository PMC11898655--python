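# poleprof

Single-cell image quantification for polar growth in rod-shaped bacteria:
axial fluorescence profiling, cell-wall-synthesis foci and septum detection,
pole asymmetry metrics, and spectral phasor analysis of hyperspectral
stacks — with a seeded synthetic scene generator that provides ground truth
for every stage.

## The problem

Mycobacteria elongate from their tips, not their sidewalls, and they do it
asymmetrically: the old pole (inherited from the mother cell) incorporates
new peptidoglycan faster and over a broader zone than the new pole (born at
the last division). Fluorescent D-amino acid probes (e.g. HADA) light up
the incorporation zones, so a dividing cell shows three intensity maxima —
two poles and the septum — and the septum sits off-center. Quantifying this
per cell requires: a medial axis and length for each cell, a
length-normalized axial intensity profile averaged across a wide line,
peak-prominence-calibrated foci detection, pole/septum landmark positions
and intensities, and a per-pole decay slope

`I(x) ≈ a − m·x` over 10 profile points from the pole peak inward,

whose magnitude `m` separates fast (gentle slope) from slow (steep slope)
poles. Membrane-environment dyes (LAURDAN) add a spectral dimension: each
pixel's emission spectrum `I_k` maps to the first-harmonic phasor

`G = Σ I_k cos(2πk/K)/ΣI_k`, `S = Σ I_k sin(2πk/K)/ΣI_k`,

where the angle Φ tracks the spectral center of mass and the modulus M the
spectral width, and two-reference linear combinations yield per-pixel
component fractions.

The package is aimed at microbiologists and image analysts who want these
measurements scripted and reproducible rather than drawn by hand, and at
method developers who need a ground-truth generator to validate peak
detection and asymmetry statistics.

## Worked example

```python
from scipy import stats
from poleprof import landmarks, synthgen, workflow

prom = None
for preset in ("control", "delta_fhaA"):
    scenes, gt = synthgen.generate_population(preset, 80, seed=31)
    pop = workflow.extract_population_profiles(scenes, "hada", ground_truth=gt)
    if prom is None:                       # calibrate once on control, freeze
        flags = [gt[c].septate for c in pop.profiles]
        prom, _ = landmarks.calibrate_prominence(list(pop.profiles.values()), flags)
    _, _, df, _ = workflow.analyze_population(pop, prom)
    sn, so = df["slope_new"].dropna(), df["slope_old"].dropna()
    print(preset, round(sn.median()), round(so.median()),
          stats.ks_2samp(sn, so).pvalue,
          round(df["pole_septum_ratio"].median(skipna=True), 2))
```

prints

```
      control: slope(new) median     861, slope(old) median     614, KS p=1.00e-04, pole/septum ratio 1.85
   delta_fhaA: slope(new) median     331, slope(old) median     396, KS p=5.71e-01, pole/septum ratio 0.69
```

(formatted as in `examples/04_pole_asymmetry.py`). Reading: in the control
phenotype the new pole decays ~40% more steeply than the old pole (KS
p ≈ 1e-4 — asymmetric growth) and polar intensity dominates the septum
(ratio 1.85); in the knockout-like phenotype the poles are statistically
indistinguishable and the septum dominates (ratio 0.69) — asymmetric polar
elongation is lost. The `examples/` directory has one short script per
capability (simulation, profiles, foci calibration, asymmetry, phasors,
full pipeline); each prints its numbers with a line on what they mean.

A thin CLI mirrors the library for shell use:

```bash
poleprof simulate --preset control --n 100 --seed 7 --out scratch/sim
poleprof run --config config.yaml --out scratch/run
```

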