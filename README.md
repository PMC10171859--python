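# remyetrack

Serial-MRI detection of remyelination in focal white-matter lesions, with a
synthetic marmoset-EAE data generator and radiological–pathological
concordance statistics.

## The problem

In multiple sclerosis and its animal models, focal inflammatory
demyelinating white-matter lesions can spontaneously remyelinate. On serial
proton density-weighted (PDw) MRI normalized to gray matter (GM = 1),
normal-appearing white matter (NAWM) sits at 0.65–0.75; a new lesion
appears as a hyperintense focus, and a remyelinating lesion returns toward
isointensity over the following weeks, while persistently demyelinated
lesions stay hyperintense. Marmoset experimental autoimmune
encephalomyelitis (EAE) recapitulates this with weekly scanning and
terminal histology, making lesion-level validation possible.

`remyetrack` implements the complete analysis chain for this setting, for
imaging scientists who want a transparent, fully testable reference
pipeline:

- **imgproc** — GM normalization (`I / mean(I_GM)`), voxelwise MTR
  (`(M0 − M_SAT)/M0`), pre/post-gadolinium T1 subtraction and enhancement
  detection, and threshold + 26-connected-component lesion segmentation
  with the standard 4-voxel (0.09 µL) minimum size filter.
- **tracking** — lesions at consecutive timepoints are the same lesion when
  their 3D masks overlap by ≥ 4 voxels; every track carries a full weekly
  trajectory of volume (µL) and mean normalized PDw intensity, with the
  maximum-extent ROI propagated before first detection and after
  disappearance.
- **mriclass** — the three-class rules: *early active* (hyperintense and
  enhancing at the terminal scan), *chronic, at least partially
  demyelinated* (hyperintense, not enhancing), *remyelinated* (previously
  hyperintense, isointense at terminal, not enhancing); the 0.5 µL
  peak-size rule; and remyelination-window estimation from the downward
  intensity slope and its plateau.
- **histo** — demyelinated area as the percentage of null-valued pixels on
  PLP/LFB stains inside a lesion-core ROI; ASPA/Olig2 cell counting
  (ASPA+/Olig2+ = mature oligodendrocyte, ASPA−/Olig2+ = OPC); three-class
  histological categorization.
- **stats** — 2×2 demyelinated-vs-remyelinated confusion matrix (positive
  class = remyelination) with sensitivity `tp/(tp+fn)` and specificity
  `tn/(tn+fp)`, Cohen's κ, point-biserial correlation with an exact
  permutation p for binary outcomes, Pearson lesion-age/OPC correlation,
  Welch t-test and one-way ANOVA.
- **synthgen** — a synthetic cohort generator emulating the study
  conditions (weekly scans, 0.0225 µL voxels, 30/25/45% class mix, 4–7-week
  demyelination, 4–9-week remyelination, class-conditional histology
  endpoints) with exact ground truth for every stage.

## Worked example

```python
from remyetrack import (ConfusionMatrix2x2, sensitivity_specificity,
                        SimulationConfig, PipelineConfig, run_pipeline)

# Reference-cohort concordance: 31 lesions with both MRI and histology
cm = ConfusionMatrix2x2(tp=9, fn=0, fp=3, tn=19)
sens, spec = sensitivity_specificity(cm)
print(f"sensitivity = {100*sens:.1f}%  specificity = {100*spec:.1f}%  "
      f"accuracy = {100*cm.accuracy:.1f}%")

# Synthetic five-subject cohort, 8 lesions each, study noise level
report = run_pipeline(PipelineConfig(
    simulation=SimulationConfig(n_lesions=8, noise_sd=0.01),
    n_subjects=5, seed=1))
vt = report["vs_ground_truth"]
print(f"lesions: {report['n_true_lesions']}  tracks: {report['n_tracks']}")
print(f"accuracy vs truth: {100*vt['classification_accuracy']:.1f}%")
```

prints

```
sensitivity = 100.0%  specificity = 86.4%  accuracy = 90.3%
lesions: 40  tracks: 40
accuracy vs truth: 100.0%
```

The first line is the published lesion-level confusion matrix: every
histologically remyelinated lesion was predicted remyelinated on MRI
(sensitivity 100%), while 3 of 22 histologically demyelinated lesions were
over-called (table-derived specificity 19/22 = 86.4%; the cohort's overall
accuracy 28/31 = 90.3% is reported alongside). The second part simulates
40 lesions across five subjects at the study noise level, re-detects each
lesion by segmentation and overlap tracking, and recovers the true
three-class label for all of them.

The same stages are available from the shell:

```bash
remyetrack simulate --out study/ --seed 5
remyetrack track --study study/ --out tracks.csv
remyetrack classify --tracks tracks.csv --out labels.csv
remyetrack run --out results/ --seed 1       # full cohort pipeline
```

## Layout

```
src/remyetrack/
  core.py      lesion-class vocabulary
  imgproc.py   voxelwise ops + segmentation
  tracking.py  longitudinal linking + trajectories
  mriclass.py  three-class MRI rules, size rule, window estimation
  histo.py     stain quantification + histological categories
  stats.py     concordance and cohort statistics
  synthgen.py  synthetic studies and histology with ground truth
  datasets.py  reference cohort tables
  pipeline.py  end-to-end driver
  io.py, cli.py
docs/methods.md  model, parameters, numerical choices, limitations
```
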