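# echoseg

Human-label-free segmentation and quantification of cardiac ultrasound.

Manual chamber tracing is the bottleneck of echocardiographic analysis:
labelling the four chambers across the standard views of even a few hundred
studies costs a trained reader months. `echoseg` implements a fully
self-supervised alternative — no human ever draws a contour:

1. **Weak labels from classical computer vision + clinical shape priors.**
   Apical views: dark blood pools extracted by smoothing, darkest-class
   thresholding within the imaging fan, morphological opening, and
   shape-prior gates (area, eccentricity, solidity, centroid position); the
   pool nearest the sector apex is the ventricle, the one beyond the valve
   plane the atrium. Short-axis view: Hough circle detection.
2. **Staged training with early-learning stopping.** Models trained on
   noisy labels fit clean structure before memorizing label noise, so each
   training run is stopped at the elbow (maximal-curvature bend) of the
   validation soft-Dice loss curve.
3. **Self-learning.** The stopped model infers on *all* frames; predictions
   that survive shape-descriptor quality control become the (larger,
   cleaner) label set for the next round. The four-chamber view is
   bootstrapped from the two-chamber model (its predictions are relabelled
   by laterality and the RV apex is stretched to known RV/LV length
   correlations); the short-axis view goes Hough circle → edge detector →
   filled edges → segmenter → epicardial/endocardial labels → final model.
4. **Clinical measurements.** Per-frame chamber areas are fitted with a
   sinusoid at the heart-rate frequency f = HR/60; the video with the best
   r² is selected, its largest-area frame is end-diastole (ED) and its
   smallest end-systole (ES). Volumes use the method of discs
   (biplane V = (π/4) Σ aᵢbᵢ · L/n, single-plane V = (π/4) Σ aᵢ² · L/n),
   LV mass the area–length formula
   m = 1.05 · (5/6) · [A_epi (L + t) − A_endo L] with
   t = √(A_epi/π) − √(A_endo/π), and LVEF = 100 · (EDV − ESV)/EDV.
   Measures are BSA-indexed and binned normal/abnormal against a
   configurable guideline threshold table.
5. **Agreement statistics.** Pearson r / r², Bland–Altman bias with ±2·SD
   limits of agreement, Cohen's κ on normal/abnormal calls, Dice overlap,
   and a seeded percentile bootstrap.

Because the clinical data such a pipeline targets cannot be redistributed,
the package ships a **synthetic echo-phantom generator**: sector-shaped
frames with dark elliptical chambers inside bright myocardial walls,
multiplicative Rayleigh speckle, optional angular signal dropout, and cine
sequences whose chamber areas follow
A(t) = A_ed − (A_ed − A_es)(1 − cos 2πft)/2 with analytic EDV/ESV/EF.
Every stage of the pipeline is therefore testable offline against closed
forms.

## Worked example

```bash
echoseg run-all --views A2C --n-studies 8 --seed 1 --out runs/demo
```

runs the full chain on eight generated two-chamber phantom studies
(speckled, 30% of studies with a dropout wedge) and prints the
coverage-weighted mean LV Dice of each stage against the phantom truth:

```
view                stage  mean_lv_dice
 A2C          labels_weak      0.789092
 A2C labels_self_learning      0.928489
 A2C         model_model1      0.990783
 A2C         model_model2      0.985327
```

Reading the table: the classical-CV weak labels overlap the true LV at
Dice 0.79 (they are coarse and skip frames the shape priors reject); the
self-learning round recruits QC-passed labels on 119 of the 128 frames; the
trained models generalize to every frame at Dice ≈ 0.99 (on this easy
eight-study suite the first model already saturates, so the second round
changes it only within noise — on harder suites the gain is larger).
`runs/demo/` also
contains `measurements.csv` (per-study LVEDV/LVESV/LVEF/LA volume versus
the phantom truth), `agreement.json` (r², Bland–Altman bias ± LOA per
measure), per-stage loss-curve CSVs, the QC log with every discarded
frame's reasons, and the final model weights.

Library use mirrors the CLI:

```python
from echoseg.datatypes import View
from echoseg.pipeline import PipelineConfig, run_end_to_end

art = run_end_to_end(PipelineConfig(views=(View.A2C,), n_studies=8, seed=1))
print(art.stage_dice)          # the table above
print(art.measurements.head()) # truth vs predicted per study and measure
```

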