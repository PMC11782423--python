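# cadeval

Standalone-performance evaluation for lesion-detection CAD systems on
volumetric (CT) data: 3D-IoU matching of findings to ground-truth nodules,
scan- and nodule-level scoring, FROC/ROC/PR analysis, Wilson /
Clopper-Pearson / Rao-Scott confidence intervals, characterization
concordance, Bland-Altman size agreement, reader-adjudication reference
standards, and a synthetic cohort + simulated-detector generator so the
whole pipeline runs and is verified without any external data.

## Modules

| module | role |
| --- | --- |
| `cadeval.annotations` | domain model (voxel masks, nodules, findings, scan metadata), validation, CSV/JSONL/NIfTI I/O, ellipsoid rasterization, diameter/volume measurement |
| `cadeval.matching` | one-to-one finding↔nodule assignment by 3D IoU (or intersection-over-finding), scan TP/FN/FP/TN labelling, cohort match tables |
| `cadeval.metrics` | Wilson, Clopper-Pearson and Rao-Scott intervals, operating-point summaries (sensitivity/specificity/precision/F1/FPPI), empirical ROC with DeLong CI, average-precision PR, FROC, subgroup sensitivity, chi-square covariate comparison |
| `cadeval.characterization` | per-class concordance of predicted texture/calcification/spiculation/lobe, detected-vs-missed profiles, stratified mean absolute size error, Bland-Altman agreement |
| `cadeval.adjudication` | report + blinded-reader discrepancy detection, arbitrator decisions, reference-standard finalization, reader-vs-CAD cross-tabulation |
| `cadeval.synthetic` | reproducible synthetic cohorts, a parameterized imperfect detector and reader, and a deterministic fixture reproducing a full published-style contingency |
| `cadeval.cli` / `cadeval.report` | `cadeval` command-line tool, pipeline orchestration, CSV/JSON report rendering |

## CLI

```bash
# generate a synthetic cohort with simulated detector output
cadeval simulate --seed 17 --out cohort/ --with-reader

# match findings to ground truth (IoU >= 0.10 by default)
cadeval match --cohort cohort/ --iou-threshold 0.10 --criterion iou --out match.json

# full evaluation: metrics.json, published-style CSV tables, curve exports
cadeval evaluate --cohort cohort/ --report out/

# reference-standard construction from report + reader + arbitrator decisions
cadeval adjudicate --report-file report.json --r1-file r1.json \
    --scans cohort/scans.csv --out adj/           # writes a decisions template
cadeval adjudicate --report-file report.json --r1-file r1.json \
    --scans cohort/scans.csv --decisions decisions.csv --out adj/

# re-render tables from an existing metrics bundle
cadeval report --metrics out/metrics.json --out tables/
```

The generator is configured by YAML (`cadeval simulate --config cfg.yaml`);
top-level keys mirror `SyntheticConfig` fields, with nested `detector:` and
`reader:` sections mirroring `DetectorProfile` / `ReaderProfile`, e.g.

```yaml
n_scans: 500
prevalence: 0.46
detector:
  sensitivity_by_texture: {solid: 0.872, part_solid: 0.894, ground_glass: 0.595}
  fp_rate_lambda: 0.274
```

## Cohort format

A cohort directory holds `scans.csv` (one row per scan: covariates,
grid shape, voxel spacing), `nodules.jsonl` and `findings.jsonl` (one JSON
record per nodule/finding with an inline run-length-encoded voxel mask or
ellipsoid parameters), and `manifest.json`. Masks can alternatively be
stored as NIfTI label volumes (`write_cohort(..., mask_format="nifti")`).
CSV annotation tables with ellipsoid parameter columns are also accepted.
All masks for a scan share one grid; coordinates are 0-based (x, y, z)
with z the slice axis.

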