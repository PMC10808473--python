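# pfahet

Intratumoral-heterogeneity analysis for posterior fossa group A (PF-EPN-A)
ependymoma, a pediatric brain tumor whose tissue often shows sharply
demarcated nodules of densely packed tumor cells inside loose, sparsely
cellular glial tissue.  The package quantifies that heterogeneity and its
clinical correlates:

- **Density compartments** — nuclei are detected in a scanned tissue image,
  a local density map ρ(x) (cells per 1,000 µm²) is built on a 28.88 µm
  grid, and grid points with ρ > 8.5 cells/1,000 µm² are classified as
  cell-dense.  Outputs: the dense-area fraction of the tissue and the
  Ki67-positive (proliferating) fraction per compartment.
- **FISH scoring** — per-nucleus test/control probe counts are scored for
  chromosome 1q gain (test ≥ 3 or test/control > 1) and 6q loss (test ≤ 1
  or test/control ≤ 0.5); an area is called aberrant when ≥ 10% of its
  (typically 100) scored nuclei are.
- **Arm-level CNV calls** — methylation-derived arm log2 ratios are called
  gained at ≥ +0.25 and lost at ≤ −0.25; paired dense/sparse calls per case
  form a 2×2 table tested with a two-sided Fisher exact test
  (point-probability method, log-space hypergeometric enumeration).
- **Survival stratification** — Kaplan–Meier curves, the two-group log-rank
  test χ² = (Σ(O₁−E₁))² / ΣV with hypergeometric tie handling, the median
  split, and the exhaustive best-cutoff scan over every dichotomization of
  a continuous covariate (a maximally selected statistic; an optional
  permutation adjustment quantifies its selection effect).
- **ROI normalization** — digital-spatial-profiling count matrices pass QC
  (aligned-read fraction, negative-probe geomean), nuclei-count scaling by
  the geometric-mean method, Q3 (75th-percentile) normalization, and
  negative-probe background correction with per-gene signal-to-noise.

Every input the pipeline consumes can also be **generated synthetically with
planted ground truth** (`pfahet.synth`): point-process tissue images with
demarcated nodules, clonal FISH mixtures, subclone-diluted arm log2 ratios,
survival cohorts with a step hazard at a known density cutoff, and ROI count
matrices with planted signatures and QC failures.  Each generator is
seed-deterministic, so every downstream stage is testable end to end without
any external data.

## Worked example

`examples/01_density_compartments.py` plants nodules over 30% of a 2 × 2 mm
field and recovers the compartments from the rendered image:

```
planted nodule fraction : 0.296
recovered dense fraction: 0.278
nuclei detected         : 20725 (planted 23426)
Ki67+ fraction, dense   : 0.291 (n=10234, planted rate 0.30)
Ki67+ fraction, sparse  : 0.045 (n=4954, planted rate 0.05)
```

The dense-area fraction recovered from detection + density mapping +
thresholding tracks the planted truth to within ~2 percentage points, and
the per-compartment Ki67 fractions recover the planted proliferation rates.
`examples/03_cnv_enrichment.py` reproduces the cohort enrichment test from
its printed counts:

```
1q gain  10/18 dense vs 3/18 sparse: p = 0.0354
6q loss   3/18 dense vs 0/18 sparse: p = 0.2286
```

The other examples cover FISH area calls (`02`), survival cutoff search
(`04`), ROI normalization (`05`), and the end-to-end cohort pipeline with a
reproducible manifest (`06`).

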