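# tvidex

Time-varying-intercept differential expression analysis for longitudinal
cohort transcriptomics.

`tvidex` detects probes (genes) whose expression trajectories differ between
two outcome groups — e.g. patients who do or do not develop in-stent
restenosis after coronary stenting — across irregularly sampled blood-draw
time courses. The mean level is modelled as a piecewise-polynomial function
of days since the intervention with a single interior knot at the median
follow-up time. A pooled (null) curve and separate per-group (alternative)
curves are fitted by least squares; the test statistic is the relative RSS
improvement `T = (RSS_null - RSS_alt) / RSS_alt`, calibrated by a residual
bootstrap that resamples residuals in whole subject blocks. Downstream
stages cover Benjamini–Hochberg / Storey FDR selection, expression-pattern
classification (consistent vs divergent group separation), replication
testing in an independent cohort (FDR within the selected set), a
random-probe-set sensitivity analysis, and Fisher/EASE category
over-representation.

Because no public accession exists for the motivating datasets, the package
ships a synthetic-cohort generator (`tvidex.synthetic_cohort`) that emulates
the two study designs — a 312-subject three-timepoint discovery cohort and a
97-subject two-timepoint replication cohort — with subject random effects,
age/sex covariate effects, a detection floor, and per-probe ground truth
(null / main-effect / interaction probes).

## Package layout

| module | contents |
| --- | --- |
| `tvidex.dataio` | TSV readers/writers: expression matrix, sample manifest, annotation, results; manifest summaries; probe→gene mapping |
| `tvidex.synthetic_cohort` | cohort designs (`CARDIOGENE`, `DECODE`, custom), manifest and expression simulation, ground-truth tables |
| `tvidex.preprocess` | low-expression floor filter, per-probe age/sex adjustment, sex-concordance QC (nearest shrunken centroid or LDA) |
| `tvidex.tvi_core` | spline basis (degree 0 or 1, one knot), nested least-squares fits, RSS-ratio statistic, subject-block residual bootstrap |
| `tvidex.discovery` | genome-wide scan, FDR q-values, significance selection, pattern classification, baseline Welch comparison |
| `tvidex.replication` | replication of a selected probe set, random-set sensitivity analysis |
| `tvidex.enrichment` | one-sided hypergeometric over-representation (Fisher and EASE modes), coverage report |
| `tvidex.cli_pipeline` | YAML config, end-to-end pipeline, `tvidex` CLI |

## Command line

```bash
# simulate a replication-style cohort
tvidex simulate --template decode --n-probes 500 --seed 1 --out-dir sim/

# QC filter + covariate adjustment
tvidex preprocess --matrix sim/matrix.tsv --manifest sim/manifest.tsv --out-dir pp/

# genome-wide time-course scan
tvidex scan --matrix pp/matrix.tsv --manifest sim/manifest.tsv \
    --bootstrap-n 10000 --seed 1 --out scan_results.tsv

# replication / sensitivity / enrichment
tvidex replicate --selected selected.txt --matrix rep/matrix.tsv --manifest rep/manifest.tsv
tvidex sensitivity --matrix rep/matrix.tsv --manifest rep/manifest.tsv --set-size 46 --iterations 100
tvidex enrich --selected genes.txt --universe universe.txt --term-ann terms.tsv

# everything, from one config
tvidex all --config pipeline.yaml --seed 1
```

Exit codes: 0 success, 2 configuration/validation error, 3 stage failure.
Bootstrap defaults are desk-scale (10,000 resamples for the scan, 2,000 for
replication); the production presets used in the original analyses
(10,000,000 and 100,000) are available through the same config keys.

## Tests

```bash
python -m pytest -q tests/
```

The suite (~1–2 min) includes unit tests per module, property/invariant
tests (partition of unity, RSS nesting, scale invariance, BH step-up oracle,
hypergeometric tail oracle), bootstrap calibration checks, and
`tests/test_acceptance.py`, which implements the acceptance criteria
(type-I error envelope, power monotonicity, degree-0 closed-form
equivalence, exhaustive FDR and enrichment oracles, replication and
sensitivity behavior).

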