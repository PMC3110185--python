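# escreen

Analysis pipeline for a mouse embryonic stem (ES) cell adherent
differentiation and cytotoxicity screen read out by two-channel In-Cell
Western imaging. The assay measures, in every well of a 96-well plate, a
cell-number stain (700 nm channel) and the cardiomyocyte differentiation
marker MYH6/MYH7 (800 nm channel); chemicals are tested in duplicate at
four concentrations (0.0125–12.5 µM) with vehicle and no-stain controls on
each plate. The package is aimed at computational toxicologists who want a
tested, reusable implementation of this style of concentration-response
screen — including a synthetic-plate generator with known ground truth for
validating every stage.

## What it computes

**Well processing.** Channel intensities are background-corrected by the
per-plate mean of no-stain wells; differentiation is the per-well 800/700
ratio (marker signal normalized to cell number); both endpoint axes are
made relative to the plate's vehicle mean.

**Activity calling and AC50.** Per chemical and axis, a control band is set
at the vehicle mean ± 2 SD. Series with excursions only below (above) the
band are fit by nonlinear least squares to a four-parameter Hill curve with
trend-specific anchoring:

    down:  y(c) = b + (1 − b) / (1 + (c/a)^h)          (top fixed at 1)
    up:    y(c) − 1 = T · (c/a)^h / (1 + (c/a)^h)      (bottom fixed at 0)

The AC50 is the concentration where the fitted curve reaches a 50% change
from control; curves that never attain it, flat series, and nonmonotone
(U-shaped) series yield an inactive call carrying the matrix default of
1 M. More generally `AC_F = AC50 · (F/(100−F))^(1/|h|)` gives the
concentration of an F-percent change.

**Association mining.** Calls populate a chemicals × assays matrix of molar
AC50s (inactive = 1 M). Columns are dichotomized (Fisher's exact test on
the 2×2 input/output table) or scored as `−log10 AC50 [M]` (Welch t-test of
input scores between output-positive and output-negative chemicals).
Pathway perturbation scores — the minimum AC50 over a pathway's assays —
join as extra columns.

**linmod classifier.** A stepwise multivariate model:
`score_c = Σ_{i≤Nmax} sign_i·x_ci − Cutoff`, predicting a chemical active
iff the score is > 0, with columns entered in order of univariate
significance. Nmax is tuned by stratified 5-fold (80/20) cross-validation
maximizing held-out ROC AUC; Cutoff maximizes balanced accuracy of the
decision rule.

The per-chemical AC50 table published for this assay (56 active chemicals
across the four endpoints) ships as a fixture and every summary statistic
is recomputed from it at test time.

## Worked example

```python
import escreen as es

summary = es.summarize_actives(es.load_table1(), library_size=309)
print(summary.summary())
```

```
Screen activity summary
=======================================================
chemicals with >= 1 AC50       56 (18.1% of 309)
AC50 values calculated         71
  below 1 uM                   18
  above 10 uM                  20
nonmonotone (U-shape)           0

endpoint         actives         min AC50 (uM)         max AC50 (uM)
--------------------------------------------------------------------
cell_loss             32      0.017 (Captafol)   17 (Difenoconazole)
cell_gain              9       0.43 (Mancozeb)    17 (Sulfentrazone)
diff_decrease         26       0.13 (Rotenone)   18 (Difenoconazole)
diff_increase          4    0.45 (Dicrotophos)       15 (Permethrin)
```

56 of 309 library chemicals (18.1%) produced at least one AC50; the most
potent cytotoxicant is Captafol at 0.017 µM and the strongest
differentiation inhibitor Rotenone at 0.13 µM. Fitting a single simulated
chemical recovers its curve:

```python
import numpy as np

chem = es.TruthChemical("Spiro-like", (es.Effect("diff_decrease", 0.5, 1.2, 1.0),))
wells = es.generate_plate(es.PlateLayoutSpec(), [chem], es.NoiseModel(seed=4))
responses = es.process_screen(wells)
series = es.ResponseSeries.from_responses(responses, "Spiro-like", "differentiation")
print(es.HillCurveModel.from_series(series, "down").fit().summary())
```

```
Hill concentration-response fit
=======================================
trend                              down
n obs                                 8
converged                          True
top                                   1
bottom                        6.732e-23
AC50 (midpoint)                  0.5125
Hill slope                        1.252
RSS                             0.00653
AC50 (50% change)                0.5125
```

The true midpoint was 0.5 µM with slope 1.2; at 5% intensity noise the fit
lands at 0.51 µM, slope 1.25. The full pipeline
(simulate → process → call → associate → model → report) runs from a YAML
config or the CLI:

```bash
escreen run --outdir demo_run --seed 1
escreen report --library-size 309       # summary of the packaged fixture
```

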