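# asymstroke

Hemispheric-asymmetry CT infarct volumetry with a downstream cohort
analysis stack: group screening statistics, L1-regularized predictor
selection with ROC/DCA validation, and network inference (graphical-lasso
partial correlations, hill-climbing directed networks with bootstrap arc
strengths, and joint baseline/outcome networks).

Everything is testable at desk scale without any external data: a phantom
module generates synthetic head CTs with known ground-truth lesions, and a
cohort module generates synthetic patient tables that emulate published
per-group summary statistics.

## Components

| Module | Purpose |
| --- | --- |
| `asymstroke.phantom` | Synthetic head CT phantoms (nested ellipsoids, optional hypodense lesion, Gaussian noise, known misalignment) and a symmetric 1 mm template. |
| `asymstroke.imaging` | The segmentation workflow: reorient to RAS, CT skull strip, 1 mm isotropic resample, HU windowing (−20..80), left–right flip rigid registration, 98th-percentile asymmetry threshold, 500 mm³ cluster filter, volume in mL, optional template alignment, QC overlay. |
| `asymstroke.cohort` | 34-indicator patient data model, validation, complete-case quality control, and the synthetic cohort generator (latent outcome model for the language-change score). |
| `asymstroke.stats` | Welch t, pooled Cohen's d, Yates-corrected chi-square, two-sided Fisher exact, bias-corrected Cramér's V, Benjamini–Hochberg adjustment, and a whole-table group screen. |
| `asymstroke.predictor` | Coordinate-descent lasso path with CV lambda selection, rank-statistic AUC with DeLong confidence intervals, confusion metrics, decision-curve analysis with bootstrap bands. |
| `asymstroke.network` | EBIC-selected graphical lasso with centrality indices (strength, closeness, betweenness, expected influence), Gaussian-BIC hill climbing, bootstrap arc strength/direction with the 51% orientation rule, and network outcome analysis. |
| `asymstroke.cli` | `asymstroke` command-line entry point. |

## CLI

```bash
# phantom with a 15 mL ground-truth lesion
asymstroke phantom --seed 1 --lesion-ml 15 --out work/phantom

# quantify a scan (config is flat YAML mirroring SegmentationConfig)
asymstroke segment --input work/phantom/phantom.nii.gz \
    --report work/report.json --mask-out work/lesion.nii.gz --qc-out work/qc.png

# synthetic cohort, group screen, predictive model, networks
asymstroke cohort simulate --seed 7 --out work/cohort.csv
asymstroke screen --cohort work/cohort.csv --group lang-improvement --out work/screen.csv
asymstroke predict --cohort work/cohort.csv --seed 7 --out work/model.json \
    --roc work/roc.csv --dca work/dca.csv
asymstroke network --cohort work/cohort.csv --mode glasso --out work/net
```

Every JSON artifact embeds the package version, seed, and a hash of the
effective configuration.

## Notes

- Registration is mono-modal mean-squared-difference, three-level
  multiresolution, Powell search; masks move by nearest neighbour,
  intensities trilinearly.
- The asymmetry threshold is taken over brain-mask voxels, and by default
  only voxels hypodense relative to their mirror are kept
  (`side_rule`, configurable).
- Tests run imaging at 2 mm resolution to stay fast; the workflow
  constants themselves are unchanged.
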