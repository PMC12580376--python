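# earlycrop

Early-season crop classification from fused optical and SAR satellite time
series, with an explicit measure of *when* in the season a crop first becomes
identifiable.

## The problem

Soybean and maize are spectrally similar through most of the growing season,
and persistent summer cloud cover leaves optical (Sentinel-2-like) time series
full of gaps exactly when the crops start to differ.  C-band SAR
(Sentinel-1-like) backscatter sees through clouds and responds to canopy
structure, but is noisy (speckle) and weaker on its own.  `earlycrop`
implements the full fusion pipeline used for in-season soybean mapping:

1. **Compositing** — irregular, partly cloud-masked observations are reduced
   to 10-day median composites on a fixed 16-window grid (DOY 121–280, May 1
   to early October), with linear interpolation across empty windows.
2. **Optical features** — per window, five vegetation indices over the
   surface-reflectance bands ρ:

   * EVI = 2.5 (ρ_NIR − ρ_red) / (ρ_NIR + 6 ρ_red − 7.5 ρ_blue + 1)
   * LSWI = (ρ_NIR − ρ_SWIR1) / (ρ_NIR + ρ_SWIR1)
   * RENDVI = (ρ_NIR − ρ_RE2) / (ρ_NIR + ρ_RE2)
   * NDSVI = (ρ_SWIR1 − ρ_red) / (ρ_SWIR1 + ρ_red)
   * REPI = 705 + 35 ((ρ_red + ρ_RE3)/2 − ρ_RE1) / (ρ_RE2 − ρ_RE1)  [nm]

   then, per sample, 6 season statistics × 11 spectral parameters, the
   "greenest"/"wettest" peak-window snapshots, first-order phase/amplitude of
   a least-squares harmonic fit f(t) = a₀ + Σₖ [aₖ cos(2πkωt) + bₖ sin(2πkωt)]
   with ω = 1.5 and t = DOY/365, median-threshold phenology (SOS/EOS/LOS) and
   accumulated EVI — 94 named features.
3. **SAR features** — σ⁰_VV and σ⁰_VH composites (dB), the linear-power ratio
   indices RVI = 4σ_VH/(σ_VH+σ_VV) and CPR = σ_VH σ_VV/(σ_VH+σ_VV), 7
   statistics × 4 parameters plus 3 temporal principal components × 4
   parameters — 40 named features.  A 7×7 refined Lee filter is provided for
   despeckling backscatter rasters.
4. **Classification** — a 100-tree random forest (minimum leaf population 10)
   on an 8:2 stratified train/validation split, with Mean-Decrease-in-Impurity
   feature ranking and top-k subset selection.
5. **Evaluation** — confusion-matrix metrics (OA, Kappa, producer's/user's
   accuracy, F1, area accuracy) and the **Earliest Identifiable Time (EIT)**:
   the series is truncated to 14 progressively longer spans (ending DOY
   150 … 280), the classifier is retrained per span, and the EIT is the end
   day of the first span whose soybean F1 exceeds 0.9.

Because real Sentinel scenes cannot ship with a package, `earlycrop` includes
a first-class **synthetic scene generator** whose per-crop seasonal curves
reproduce the field signatures that make the method work — rice's flooding
depression in SWIR and backscatter (DOY 120–200), soybean's VH/CPR excess over
maize after canopy closure (DOY 200–260), cloud-driven optical gaps and
gamma-distributed speckle.  Every stage of the pipeline is tested end-to-end
against it.

## Worked example

```python
import earlycrop as ec
from earlycrop import pipeline

scene = ec.generate_scene(ec.SceneConfig(seed=1))      # 1,424 labelled samples
reports = pipeline.run_classification(scene, seed=1)   # full season, 3 sources
for src, rep in reports.items():
    print(src, round(rep.oa, 4), round(rep.f1["soybean"], 4))
```

prints

```
optical 1.0 1.0
sar 0.9579 0.9504
multi 1.0 1.0
```

i.e. on a full season of this synthetic scene the fused and optical feature
sets identify soybean essentially perfectly while SAR alone trails (speckle
and per-field variability cap it) — the source ordering the method is
designed around.  The temporal sweep shows *when* identification
becomes possible:

```python
result = pipeline.temporal_sweep(scene, seed=1)
print(result.eit)        # {'optical': 220, 'sar': 230, 'multi': 210}
```

The fused series crosses the F1 = 0.9 threshold at DOY 210, right after the
soybean/maize canopy contrast switches on near DOY 200; optical alone needs
another window or two of the season.

The `examples/` directory holds four short narrative scripts (scene
simulation, compositing + features, classification + ranking, EIT sweep), and
the `earlycrop` command exposes the same stages as subcommands
(`simulate`, `composite`, `features`, `train`, `classify`, `evaluate`,
`eit-sweep`), all reading and writing plain CSV/YAML/JSON.

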