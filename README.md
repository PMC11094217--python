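# hossnf

Heap-optimizer segmentation and self-systematized neuro-fuzzy classification
of single-cell Pap-smear images.

## The problem

Cervical cancer screening by Pap smear rests on grading individual cervical
cells: three normal morphologies (intermediate squamous, normal columnar,
normal squamous) and four abnormal grades (low/moderate/high-grade dysplasia,
carcinoma in situ). Two visual cues carry most of the signal — the
nucleus-to-cytoplasm (N/C) area ratio, which rises with dysplasia grade, and
the chromatin texture of the darkly stained nucleus. `hossnf` implements a
classical (non-deep-learning) pipeline for this task, aimed at researchers
who want an inspectable, fully deterministic baseline:

1. **Preprocessing** — median filtering, wavelet shrinkage with the universal
   threshold, min–max normalization.
2. **Segmentation** — multilevel thresholding: a heap-based optimizer (HBO)
   searches threshold space for the partition maximizing Otsu between-class
   variance (default) or Kapur entropy; the darkest class is the nucleus.
3. **Texture features** — a fixed 58-value vector: 32 Haralick GLCM
   statistics (contrast/energy/entropy/correlation at distances {1,2} ×
   angles {0°,45°,90°,135°}), a 10-bin uniform-LBP histogram, and mean/std
   responses of a 5×5 Gabor bank (2 frequencies × 4 orientations).
4. **Classification** — a six-layer TSK-style neural fuzzy network with
   Gaussian antecedents: rule firing f_j = exp(−Σ_m (x_m−d_jm)²/σ_jm²),
   normalized onto the simplex, linear consequents, per-class summation and
   argmax. Structure is learned online (a rule grows where no existing rule
   fires above a novelty threshold); all parameters are then fitted
   derivative-free by the HBO.
5. **Evaluation** — binary normal-vs-abnormal specificity, sensitivity,
   accuracy, precision/PPV and NPV, plus the full 7×7 confusion matrix.

The heap-based optimizer models a corporate hierarchy: agents sit in a
fitness-keyed d-ary min-heap; per dimension each agent keeps its coordinate,
steps toward its heap parent, or steps relative to a random sibling, with a
periodic step-size coefficient γ ∈ [0, 2] and greedy acceptance.

A synthetic phantom generator (elliptical nucleus inside elliptical
cytoplasm, class-dependent N/C ratio and texture, Gaussian noise, exact
ground-truth masks) makes the whole pipeline buildable and testable without
any external dataset.

## Worked example

```python
import json
from hossnf import synth, evaluate

# 10 phantoms per class (70 images), 70/30 train/test, noise sd 5
manifest = synth.generate_dataset(
    10, "demo", seed=0, noise_sigma=5.0, split_fractions=(0.7, 0.3, 0.0),
)
report = evaluate.run_pipeline(
    {"seed": 1, "data": {"manifest": "demo/manifest.csv"},
     "ssnf": {"budget": 1000}},
    "demo_run",
)
print(json.dumps(report["binary"], indent=1))
print("mean nucleus Dice (test):", round(report["mean_nucleus_dice_test"], 4))
```

prints

```
{
 "specificity": 1.0,
 "sensitivity": 1.0,
 "accuracy": 1.0,
 "precision": 1.0,
 "npv": 1.0
}
mean nucleus Dice (test): 0.9991
```

i.e. every held-out phantom lands on the correct side of the
normal/abnormal boundary, and the thresholded nucleus masks overlap the
ground truth almost perfectly (Dice 1.0 would be pixel-identical). The run
directory holds `features.csv`, `model.json`, `predictions.csv` and
`metrics.json` (which adds the 7×7 confusion matrix and per-class tables).

The same pipeline is available from the shell:

```bash
hossnf synth --n-per-class 10 --out demo --seed 0
hossnf run --config run.yaml --out demo_run
hossnf segment --in cell.png --out mask.png --objective otsu --seed 1
hossnf features --in roi.png --out features.csv
```

## Scope and limitations

Segmentation is single-cell multilevel thresholding — no overlapping-cell
splitting or contour refinement. The classifier is trained derivative-free;
no gradient methods, rule pruning or score calibration. Phantoms emulate
intensity statistics, not real chromatin morphology; see `docs/methods.md`
for what the synthetic results do and do not demonstrate.
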