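# histoclock

Epigenetic clocks from histone-modification ChIP-seq. `histoclock` takes
replicated peak calls and per-peak read counts for marks such as H3K27ac,
builds a consensus peak feature space, normalizes and batch-corrects the
signal, screens peaks for age association, trains sparse elastic-net age
predictors under age-stratified leave-one-group-out cross-validation, and
stress-tests the resulting clocks with noise-robustness, benchmarking, and
sample-size saturation protocols. It also quantifies two structural
signatures of chromatin aging: nonlinear signal trajectories (LOESS
inflection detection) and super-enhancer fragmentation across age groups.

It is written for computational biologists who have ChIP-seq peak calls and
count matrices in hand (peak calling and alignment are upstream, out of
scope) and want a reproducible, testable route from counts to a validated
age clock. A full synthetic-data generator with ground truth is included,
so every stage can be exercised and calibrated without any controlled-access
data.

## The model

Per-peak read densities `d = c / (L/1000) / (R/1e6)` (reads per kb per
million reads-in-peaks) are log2-transformed and background-subtracted,
batch-corrected with a covariate-preserving empirical-Bayes location/scale
model (ComBat-style), and fed to an elastic net

    min over (w, b) of  (1/2n) Σ_j (y_j − w·x_j − b)²  +  λ (α‖w‖₁ + (1−α)/2 ‖w‖₂²)

predicting chronological age `y` from standardized peak signal `x`.
Hyperparameters (α, λ) minimize pooled RMSE under leave-one-group-out CV
over 11 equal-width age strata. Age association of individual peaks is
screened with Spearman's ρ (candidates: |ρ| ≥ 0.5, p ≤ 0.05 after
Benjamini–Hochberg reporting), and the age gap `ŷ − y` and paired scaled
age gap `(ŷ_post − ŷ_pre)/ŷ_pre` quantify accelerated or reversed aging.
See `docs/methods.md` for every convention and default.

## Worked example

```python
import numpy as np
from histoclock import (
    SimulationConfig, generate, quantify_density, log2_background_subtract,
    spearman_screen, candidate_filter, logo_cv_train,
)

cfg = SimulationConfig(n_peaks=2000, n_samples=100, fraction_linear=0.05,
                       age_range=(5.0, 75.0), seed=7)
sim = generate(cfg)                       # peaks, counts, sample sheet, truth
mat = log2_background_subtract(quantify_density(sim.matrix))

table = candidate_filter(spearman_screen(mat))
print("candidates:", int(table.is_candidate.sum()))

model, cv = logo_cv_train(mat, alpha_grid=[0.1, 0.5, 1.0],
                          n_lambda=20, n_groups=11)
print(f"CV r={cv.pearson_r:.3f}  MAE={cv.mae:.2f} y  RMSE={cv.rmse:.2f} y  "
      f"features={model.n_features}")
```

Output on this seed:

```
candidates: 100
CV r=0.994  MAE=1.77 y  RMSE=2.28 y  features=146
```

All 100 planted age-informative peaks (and nothing else) pass the joint
|ρ| ≥ 0.5 / p ≤ 0.05 filter. The cross-validated clock predicts held-out
ages to an average error under 2 years at this noise level, retaining 146
nonzero coefficients out of 2,000 peaks — a sparse, discrete feature set,
which is the point of the elastic net.

The same workflow runs from the shell on files:

```bash
histoclock simulate --out demo --seed 7
histoclock quantify --counts demo/counts.tsv --samples demo/samples.tsv --out demo/matrix.tsv
histoclock screen   --matrix demo/matrix.tsv --samples demo/samples.tsv --out demo/screen.tsv
histoclock train    --matrix demo/matrix.tsv --samples demo/samples.tsv --out demo/model.json
histoclock run      --config pipeline.yaml   # full pipeline + provenance manifest
```

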