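# kcqi — composite kiwifruit quality from hyperspectral reflectance

Kiwifruit on the retail shelf soften, sweeten and lose colour saturation in
a tightly coupled way: soluble solids content (SSC) rises while firmness
(F), lightness (L\*), yellowness (b\*) and chroma (C) fall.  Grading fruit
on any single parameter misses this joint evolution.  This package builds a
**kiwifruit comprehensive quality index**

```
KCQI = ln( 1000 · F · L* · b* · C / SSC )
```

from destructive reference measurements via factor analysis (Pearson
screening, KMO/Bartlett adequacy gates, varimax-rotated principal-component
factors, loading-threshold selection) and then predicts it
**non-destructively** from 400–1000 nm reflectance spectra: SPXY
calibration/prediction partitioning, characteristic-band selection (SPA,
CARS, random frog), regression with PLSR, random forests or a 1-D
convolutional network, and pixel-wise index maps rendered over the fruit
surface.  It is aimed at chemometricians and postharvest researchers who
want a fully testable, end-to-end reference implementation of this
workflow.

Because no public dataset accompanies the study design, the package ships a
first-class synthetic-data module that reproduces the experiment's
statistical structure — 2 cultivars × 4 shelf-life days × 30 fruits, the
published quality-parameter trajectories and pooled correlation matrix
(e.g. r(SSC, F) ≈ −0.78, r(b\*, C) ≈ 0.99), and VNIR spectra with
chlorophyll dips at 420/670 nm, a declining NIR shoulder at 830 nm and the
970 nm water band.  Every pipeline stage is exercised against it; see
`docs/methods.md` for the generative model and its limits.

## Worked example

```python
import numpy as np
from kcqi import (SimConfig, simulate_quality_table, simulate_spectra,
                  add_kcqi_column, spxy_split, CARSSelector, fit_cnn1d,
                  evaluate)

cfg = SimConfig(seed=1)                       # 240 fruits, 256 bands
table = add_kcqi_column(simulate_quality_table(cfg))
print(table.groupby("day")["kcqi"].mean().round(2))
#  day
#  0    17.79
#  3    17.34
#  6    16.69
#  9    16.14

X = simulate_spectra(table, cfg)              # ROI-mean spectra (240, 256)
y = table["kcqi"].to_numpy()
cal, pred = spxy_split(X, y, 0.8)             # 192 / 48

sel = CARSSelector(random_state=7).fit(X[cal], y[cal])
fit = fit_cnn1d(X[cal][:, sel.indices_], y[cal], random_state=7)
m = evaluate(fit.model, X[pred][:, sel.indices_], y[pred], with_rpd=True)
print(f"RP2={m.r2:.3f}  RMSEP={m.rmse:.3f}  RPD={m.rpd:.2f}")
```

On the default configuration the mean KCQI falls monotonically from day 0
to day 9 (fruit ripening), CARS retains a few dozen characteristic bands,
and the CARS + 1D-CNN model reaches a prediction-set R² around 0.92 ± 0.02
with RPD well above 2 — i.e. a quantitatively usable model of composite
quality from spectra alone.  `run_all(PipelineConfig(...))` executes the
whole study grid (3 selectors × 3 models plus a full-spectrum CNN
baseline) and writes CSV/JSON reports and pseudocolor KCQI maps; the same
pipeline is available from the shell as `kcqi run-all`, with `kcqi
simulate`, `kcqi build-index` and `kcqi select-bands` exposing the
individual stages.

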