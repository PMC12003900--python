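# ramantdm

Resonance-Raman therapeutic drug monitoring (TDM) of the β-lactam
antibiotic **piperacillin in human urine**: spectral preprocessing, PLS
concentration calibration, estimation of the concentration losses caused
by clinical sample-preparation steps, donor-sex classification, and
reference-matrix-dependent detection limits — with a seeded synthetic
urine-spectrum generator so every analysis runs end to end without
instrument data.

## Who this is for

Deep-UV resonance Raman spectroscopy can quantify antibiotics in body
fluids fast enough for dose individualization in critically ill patients.
Two practical questions stand between a calibration curve and a clinical
measurement:

1. **Sample preparation changes the answer.** Freezing, centrifugation and
   filtration each remove a few percent of the drug. If calibration
   samples and patient samples are prepared differently, predictions are
   biased by exactly that loss.
2. **The reference matrix changes the answer.** Urine composition
   (urea, creatinine, uric acid) differs between donors and between sexes;
   quantifying against the wrong background urine degrades the detection
   limit.

`ramantdm` implements the statistics that quantify both effects.

## The statistics at the core

**Loss factor.** With set concentrations `c_set` and PLS-predicted
concentrations `c_pred` of treated aliquots, the fractional loss f of a
preparation step minimizes

    RMSEP(f) = sqrt( 1/n · Σᵢ ( c_set,i − c_pred,i / (1 − f) )² )

solved in closed form through the origin-regression slope
`a* = Σ c_set·c_pred / Σ c_pred²`, `f = 1 − 1/a*`, and reported as the
median ± MAD over repeated 80 % subsets. Sequential steps compose as
`1 − f_total = Π (1 − fₖ)`.

**ICH detection limits.** Fitted marker-band amplitudes (Gaussian at
~1485 cm⁻¹ on urea-normalized difference spectra) against concentration
give an OLS line with slope m and intercept standard error σₙ:

    LoD = 3.3·σₙ/m      LoQ = 10·σₙ/m

**Classification.** PCA-reduced, vector-normalized spectra are classified
by LDA and SVMs (linear cost 1000; radial cost 10 000, γ = 1), scored by
threshold-averaged ROC over 20 donor-grouped cross-validation repeats.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
from ramantdm import ExperimentConfig, run_factor_experiment

cfg = ExperimentConfig(seed=1)
cfg.synthetic.seed = 1
report = run_factor_experiment(cfg)
print(report.round(4).to_string(index=False))
```

```
treatment  factor_percent  factor_mad_percent  rmsep_before_uM  rmsep_after_uM  n  n_components  true_factor_percent
     froz          8.3661              0.0271          84.6069          5.9750 24             3                 8.42
     filt          2.2641              0.0405          23.1599          5.1380 24             3                 2.36
     cent          2.7209              0.0275          27.9083          5.7013 24             4                 2.80
filt_cent          4.7547              0.0297          48.0342          5.6493 24             5                 5.05
```

Each row is one preparation treatment: the generator renders a paired
calibration experiment (untreated reference series and a treated series
whose effective concentrations are scaled by the true loss factor in the
last column), the preprocessing chain and a PLS model turn treated spectra
into predicted concentrations, and the loss-factor statistic recovers the
scaling. `rmsep_before_uM` is the prediction error against the set values
before correction — dominated by the uncorrected loss — and
`rmsep_after_uM` the residual error after dividing predictions by (1−f):
freezing removes ~8.4 % of the drug, and correcting for it shrinks the
prediction error from ~85 µM to ~6 µM.

The same config drives the classification experiment:

```python
from ramantdm import run_classification_experiment
summary, rocs = run_classification_experiment(cfg)
print(summary.round(4).to_string(index=False))
```

```
classifier  auc_mean  auc_sd  n_repeats
       lda    0.6251  0.1882         20
svm_linear    0.6514  0.2119         20
svm_radial    1.0000  0.0000         20
```

Donor sex in the synthetic cohort is encoded nonlinearly in composition
ratios, so linear classifiers hover far below the radial-kernel SVM,
which separates the sexes perfectly in every cross-validation repeat.

A command-line interface mirrors the library:

```bash
ramantdm run-experiment factor --seed 1 --out results/
ramantdm simulate --out sim/ --seed 1          # emit synthetic spectra as CSV
ramantdm preprocess sim/spectra.csv --out prep/
ramantdm classify prep/preprocessed.csv --out cls/
```

## Layout

```
src/ramantdm/
  core_io.py          spectrum data model, long/wide CSV I/O, median spectra
  synthetic_urine.py  seeded generator of urine Raman spectra
  preprocess.py       calibration, truncation, Savitzky-Golay, EMSC, SNIP,
                      normalization
  quant_pls.py        PLS calibration with CV component selection, RMSEP
  treatment_factor.py loss-factor statistic and its cross-validation
  sex_classify.py     PCA, LDA/SVM, threshold-averaged ROC, weighting vectors
  peak_quant.py       difference spectra, marker-band fit, ICH LoD/LoQ
  pipeline.py         seeded end-to-end experiments and reports
  cli.py              typer CLI over the pipelines
```
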