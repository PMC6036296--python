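# granuflux

Functional metabolic profiling of granulocytes (eosinophils, neutrophils)
from kinetic extracellular-flux plate assays.

Extracellular-flux analysers report, per well and measurement cycle, an
extracellular acidification rate (ECAR, mpH/min — a proxy for glycolytic
lactate/H⁺ export) and an oxygen consumption rate (OCR, pmol O₂/min — a
proxy for mitochondrial respiration plus non-mitochondrial oxygen use).
Compounds injected between cycles (glucose, oligomycin, FCCP,
rotenone/antimycin A, 2-deoxy-D-glucose, or agonists such as PMA, fMLP and
PAF) partition each trace into analysis windows from which the standard
bioenergetic parameters are derived.  `granuflux` implements that analysis
for granulocyte assays, where respiratory-burst responses, ambient hypoxia
and priming cytokines add wrinkles that generic spreadsheet workflows
handle poorly.

## What it computes

**Glycolysis stress test** (ECAR; glucose → oligomycin → 2-DG):
non-glycolytic acidification NGA = ECAR before glucose; glycolysis
G = max post-glucose ECAR − NGA; glycolytic capacity GC = max
post-oligomycin ECAR − NGA; glycolytic reserve GR = GC − G.

**Mitochondrial stress test** (OCR; oligomycin → FCCP → Rot/AA):
non-mitochondrial OCR = min OCR after Rot/AA; basal respiration
BR = last pre-oligomycin OCR − non-mito; proton leak PL = min
post-oligomycin OCR − non-mito; ATP-linked respiration = BR − PL; maximum
respiratory capacity = max post-FCCP OCR − non-mito; spare respiratory
capacity = max capacity − BR.  Parameters are computed per well, then
aggregated as mean ± SEM; negative values (e.g. spare capacity under
hypoxia) are reported as computed, never clamped.

**Agonist responses**: absolute peak-height OCR after a stimulus,
baseline-subtracted delta, trapezoidal AUC above baseline, and a
transient / sustained / biphasic kinetic classification.  For
primer-then-stimulus schedules (IL-5 or GM-CSF before PAF/fMLP) the
baseline is read before the first injection of the pair.

**Hypoxia correction**: sodium-sulfite reference wells pin the sensor's
zero-oxygen reading; a two-anchor affine calibration plus a
diffusion-corrected least-squares estimator recovers OCR from raw
microchamber oxygen levels, which is essential when the ambient tension is
a fraction of a kPa (r = Vα·(k_d·(C_amb − C̄) − slope)).

**Area-ratio morphometry**: the ratio of convex-hull area to cell-contour
area from deformability-cytometry contours — 1 for convex resting cells,
rising with membrane protrusions (a shape-change/priming surrogate).

**Group statistics**: Shapiro–Wilk-gated comparisons (Student's t or
Mann–Whitney U; one-way ANOVA with Tukey HSD for ≥3 groups) and
fold-change summaries.

A ground-truth simulator (`granuflux.synthetic_flux`) generates whole
plates — processed rate traces or raw microchamber oxygen levels — from
named presets whose true levels encode published group means for human
eosinophil and neutrophil assays, so every pipeline stage can be validated
against known truth.

## Worked example

Simulate a six-well eosinophil glycolysis-stress plate (10 mM glucose) and
extract the per-well parameters:

```python
import numpy as np
import granuflux as gf
from granuflux import NoiseModel

assay = gf.simulate_rate_plate(gf.get_preset("eos_glyco_10mM"),
                               n_wells=6, noise=NoiseModel(seed=1))
for well, tr in assay.traces.items():
    p = gf.glyco_params(tr, assay.schedule)
    print(f"{well:5s} {p.nga:6.1f} {p.g:6.1f} {p.gc:6.1f} {p.gr:6.1f}")
peaks = [gf.post_glucose_peak(tr, assay.schedule) for tr in assay.traces.values()]
print(f"post-glucose peak ECAR: {np.mean(peaks):.1f} +/- "
      f"{np.std(peaks, ddof=1)/np.sqrt(len(peaks)):.1f} mpH/min (n={len(peaks)})")
```

```
A1      11.2   31.6   34.3    2.6
A2      12.5   30.5   33.6    3.1
A3      11.1   29.1   31.4    2.3
A4      11.6   32.4   33.7    1.2
A5      11.5   32.5   35.0    2.4
A6      12.2   30.5   32.2    1.7
post-glucose peak ECAR: 42.8 +/- 0.6 mpH/min (n=6)
```

NGA sits near the preset's 12 mpH/min baseline, glycolysis around
30 mpH/min with a small reserve (granulocytes run close to glycolytic
capacity), and the mean post-glucose peak lands on the preset's true
41.6 mpH/min within well-to-well noise.

The same analyses are available from the shell:

```sh
granuflux simulate --preset eos_glyco_10mM --n-wells 6 --seed 1 \
    --out rates.csv --schedule-out schedule.csv
granuflux glyco --rates rates.csv --schedule schedule.csv --out params.csv
granuflux simulate --list        # presets and their encoded truths
```

## Layout

- `granuflux.flux_core` — data model, canonical CSV dialect, window
  segmentation, well→group aggregation, density normalization
- `granuflux.stress_params` — glycolytic/oxidative parameter engine
- `granuflux.agonist_response` — peak height, kinetics, glucose oxidation
- `granuflux.hypoxia` — sulfite zero calibration, level→rate estimation
- `granuflux.synthetic_flux` — plate simulator and preset library
- `granuflux.morpho_rheo` — contour area-ratio morphometry
- `granuflux.group_stats` — gated comparisons and fold changes
- `granuflux.recovery` — simulate-and-remeasure benchmark helpers
- `granuflux.cli` — `granuflux` command-line interface

See `docs/methods.md` for the models, defaults and their rationale.
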