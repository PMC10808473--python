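# Methods

This note documents the models and procedures implemented in `pfahet`, the
defaults they use, the design choices made where more than one reading was
defensible, and what the synthetic generators do and do not emulate.

## Tissue model and density compartmentalization

**Synthetic tissue.** A field of W × H µm (default 2 × 2 mm) is populated by
two homogeneous Poisson point processes: a background process over the whole
field at `background_density` (default 2 cells/1,000 µm², loose glial
tissue) and a top-up process inside a nodule mask that raises the total
intensity there to `nodule_density` (default 15 cells/1,000 µm², densely
packed tumor nodules).  The nodule mask is a union of random discs
(150–300 µm radius) grown until it covers `nodule_fraction` of the field to
within about half a percentage point; discs that would overshoot the
tolerance band are shrunk before placement.  This reproduces sharply
demarcated compartments with a controllable area fraction.  Each nucleus is
rendered as a Gaussian blob of σ = `nucleus_radius_um` / 2 (default radius
3 µm) at a pixel scale of 1 µm/px, and carries a Ki67 flag drawn with its
compartment's rate (defaults 0.30 dense / 0.05 sparse).  The default
densities deliberately place the operating classification threshold of
8.5 cells/1,000 µm² at the mixture midpoint, so kernel smoothing at the
compartment boundary displaces it symmetrically and the recovered dense
fraction is unbiased.

Non-goals of the generator: H&E color rendering, nucleus shape/texture,
stain variability.  Consequently, passing recovery tests demonstrates that
the detection → density → classification chain is correct and well
calibrated on idealized two-channel images; it does not demonstrate
robustness to staining artifacts or stain-vector variation in real slides.

**Nucleus detection.** The rendered blur kernel is known, so detection
first applies a regularized Wiener deconvolution (regularization ε = 10⁻³,
normalized so an isolated nucleus sharpens back to a unit peak) and then
takes local maxima above 0.5.  Deconvolution separates touching nuclei:
on densely packed synthetic tissue (15 cells/1,000 µm², mean nearest-
neighbour spacing ≈ 4 µm) recall rises from ~0.73 to ~0.86 at precision
> 0.99; nuclei closer than the pixel scale remain physically unresolvable.
Ki67 positivity is read from the deconvolved Ki67 channel at the detected
peak (threshold 0.65).  The threshold sits above the midpoint because
merged detections of a positive/negative pair otherwise inflate the
positive rate; 0.65 balances the false-positive and false-negative flag
rates on packed tissue (residual bias < 1 pp either way).

**Density map.** The local density at each grid point (spacing 28.88 µm,
matching the original analysis resolution) is the number of detected nuclei
within a disc of `radius_um` (default 50 µm) divided by the disc area in
µm², × 1,000.  Discs reaching past the field edge are clipped to the field
(exact circle–rectangle intersection via shapely) so edge estimates stay
unbiased.  The 50 µm default holds ≈ 24 nuclei at threshold density —
enough for a stable estimate — while remaining small against the 150–300 µm
nodule scale so demarcation lines stay sharp.

**Classification.** A grid point is cell-dense iff its density strictly
exceeds the threshold ("more than 8.5"); the value 8.5 itself classifies
sparse.  The dense-area fraction is computed over the tissue mask only; the
default mask for synthetic fields is the full field, and
`tissue_mask_from_image` (coarse intensity threshold + morphological
closing) is available for images with empty regions.

**Ki67 per compartment.** The fraction of Ki67-positive nuclei among all
nuclei whose coordinates fall in each compartment; a compartment with no
nuclei reports NaN, not 0.  With `boundary_margin_cells` > 0, nuclei within
that many grid cells of the dense/sparse boundary are excluded from both
compartments — the analogue of sampling representative fields well inside
each region rather than in the ambiguous transition zone, where the
smoothed density estimate mixes the two populations.

## FISH scoring

A nucleus is scored 1q-gained iff it shows ≥ 3 test-probe signals or a
test/control ratio strictly greater than 1; 6q-lost iff it shows ≤ 1 test
signal or a ratio ≤ 0.5 (inclusive).  The comparators follow the printed
protocol exactly; note the asymmetry (strict for the gain ratio, inclusive
for the loss ratio) and that a nucleus such as (4, 5) — count branch
satisfied but ratio < 1 — is a gain via the count branch.  A nucleus with
zero control signals is treated as a hybridization failure for the ratio
branch: the branch is skipped with a warning rather than read as an
infinite ratio, and the count branch still applies.  An area (protocol:
100 non-overlapping intact nuclei) is called aberrant when at least 10% of
scored nuclei are — inclusive, so 10/100 is aberrant and 9/100 is not.

The clonal generator gives each nucleus the aberrant pattern (1q: 3/2,
6q: 1/2) with the area's clone fraction, diploid 2/2 otherwise, then
perturbs each count by ±1 with probability `probe_noise` (floored at 0) —
the simplest perturbation that exercises the scoring boundaries.

## Arm-level CNV and enrichment

Arm calls use inclusive cutoffs: gain iff log2 ≥ +0.25, loss iff ≤ −0.25.
The protocol states the cutoff values without comparator direction;
inclusive was chosen so the stated cutoff itself triggers a call.  When
multiple segments per arm are supplied, the arm value is their
length-weighted mean.  The dilution model behind the generator mixes clone
and diploid copy number linearly before the log: a one-copy gain at clone
fraction f gives log2(1 + f/2), a loss gives log2(1 − f/2).

The paired dense/sparse 2×2 table (one dense and one sparse call per case,
enforced) is tested with a two-sided Fisher exact test implemented by
direct enumeration: all tables with the observed margins, log-space
factorials (gammaln), summing point probabilities ≤ that of the observed
table with relative tolerance 10⁻⁷ on the comparison (the conventional
point-probability two-sided rule).  A table degenerate in a row or column
margin admits a single configuration and returns p = 1 by convention.  The
implementation reproduces both published p-values from the published
counts — 0.035 for 1q (10/18 vs 3/18) and 0.2286 for 6q (3/18 vs 0/18, the
closed form 2·C(33,15)/C(36,18)) — and matches a brute-force hypergeometric
enumeration for every 2×2 table with N ≤ 40.

`novel_at_relapse` flags a case when the relapse carries a 1q gain or 6q
loss absent from its paired primary.

## Survival analysis

Kaplan–Meier estimation uses the product-limit form with simultaneous
risk-set reduction at tied event times; censorings at an event time leave
the risk set after the events.  The two-group log-rank test accumulates
observed-minus-expected events in one group over distinct event times with
hypergeometric variance, referring (ΣO−E)²/ΣV to χ²₁; ties are handled by
the hypergeometric formulation.  The implementation agrees with lifelines
to machine precision and with a naive per-event-time oracle on exhaustive
small tie patterns.

The median split assigns "low" to covariates strictly below the median and
"high" at or above it — deterministic under ties, and an n/2 vs n/2 split
for even cohorts with distinct values.  The best-cutoff search enumerates
midpoints between consecutive distinct covariate values (every possible
dichotomization exactly once), computes the log-rank p at each admissible
cutoff (both groups ≥ `min_group_size`, default 1), and returns the
smallest p; ties resolve to the smallest cutoff.  The scanned minimum is a
maximally selected statistic and strongly anti-conservative — under the
null its median across replicates falls below 0.05 — so the module also
exposes a permutation-adjusted p (B permutations of the covariate,
add-one estimator) as a clearly separated extension; no multiplicity
correction is applied to the primary `best_p` itself.

The cohort generator draws the covariate uniform on [0,1] and event times
exponential with hazard `baseline_hazard` × `hazard_ratio`^(covariate ≥
cutoff) (defaults 0.02/month, HR 4, cutoff 0.7), with independent
exponential censoring (0.01/month) truncated at 120 months — an exact
match to the step-stratification the search must recover, not a model of
real PF-EPN-A hazard shapes.

## ROI normalization

The processing chain is fixed: QC → nuclei scaling → Q3 → background
correction, recorded in the output metadata.  QC fails an ROI iff its
aligned-read fraction < 0.8 or the geometric mean of its negative probes
< 1.0 (both configurable; the protocol source states no thresholds).
Negative-probe summaries use the zero-robust geometric mean
geomean(x + 1) − 1, which equals the plain geomean for large counts but
tolerates the occasional zero count a real probe panel produces.

Nuclei scaling multiplies ROI i by geomean(nuclei)/nucleiᵢ, so the factor
family has geometric mean 1.  Q3 normalization computes each ROI's
linear-interpolation 75th percentile over gene targets only (negative
probes excluded — the standard DSP reading of a per-ROI Q3 factor) and
scales by geomean(Q3)/Q3ᵢ, after which every ROI's Q3 equals the
pre-normalization geometric mean; an ROI with Q3 = 0 is flagged, excluded
from the geomean, and left unscaled (NaN factor).  Background correction
estimates backgroundᵢ as the (zero-robust) geomean of ROI i's negative
probes and either subtracts it with a floor at zero (default) or divides
by it (`method="snr"`); the per-gene signal-to-noise matrix is returned in
both modes so an SNR cutoff can be applied instead of subtraction — the
one-sentence protocol description is ambiguous between the two readings,
so both are exposed.

Each step records itself in the RoiSet metadata and is a no-op when applied
again, making every step — and the whole chain — idempotent on its own
output.  This is the only reading under which idempotence can hold for
covariate-driven steps (re-scaling by nuclei counts or re-subtracting a
background would otherwise change the data on every application).

`rank_genes` provides a rank-based dense-vs-sparse comparison (Mann–Whitney
rank-biserial per gene) for signature-recovery checks; no differential-
expression model is fitted.  The generator draws negative-binomial counts
(dispersion 0.1) with ROI size factors proportional to Poisson nuclei
counts (means 400 dense / 200 sparse), multiplies the first
`dense_signature_genes` genes by `signature_fold` in dense ROIs, draws
negative probes from the background distribution only (mean 5 per probe,
scaled by ROI size), and can plant QC failures (aligned fraction drawn
below 0.7, or negative-probe mean dropped to 0.2); healthy aligned
fractions are Beta(70, 3), which clears a 0.8 QC bar with overwhelming
probability so planted failures are the only failures by design.

## Pipeline

`run_cohort` executes density → FISH → CNV → survival (and ROI
normalization when ROI data are present) from a single YAML/dict config,
generating synthetic inputs or loading user CSVs.  Stages with missing
inputs are skipped with a logged notice.  Every module parameter is
surfaced with its protocol value as the default (8.5, 28.88, 0.10, ±0.25,
min_group_size 1).  All artifacts are CSV/TSV; the manifest records
parameters, seeds, and SHA-256 hashes of every output and contains no
timestamps, so a re-run with the same config is byte-identical.

## Problem sizes and numerical choices

Synthetic recovery checks use 2 × 2 mm fields (≈ 13k–45k nuclei depending
on the planted fraction) for dense-fraction recovery, and 700 × 700 µm
fields for Ki67-rate recovery — chosen so each compartment holds several
hundred nuclei, the scale at which a per-case proliferative index is
typically assessed, and at which the binomial sampling interval is wide
enough to absorb the ~1 pp residual flag error that detection merging
causes in packed regions.  Survival calibration uses 500 null replicates
at n = 60; cutoff recovery uses 50 replicates at n = 120 with the planted
cutoff at 0.7.  The exhaustive Fisher cross-check covers all tables with
N ≤ 40.  Floating-point comparisons in the Fisher sum use a 10⁻⁷ relative
tolerance on point-probability ties; normalization idempotence is asserted
to 10⁻⁹.

## Known limitations

- Detection merging is physical: nuclei closer than the pixel scale cannot
  be separated, so counts in packed regions are biased low by ~10–15% and
  per-nucleus marker flags in those regions carry a ~1 pp error after
  threshold balancing.  Real-slide performance additionally depends on
  staining quality, which the generator does not model.
- The density threshold, grid resolution, FISH comparators, CNV cutoffs and
  the 10% area rule are protocol constants, not fitted quantities; applying
  them to other tumor entities requires re-calibration.
- The best-cutoff p is reported unadjusted by design; it should never be
  interpreted as a calibrated significance level (use the permutation
  adjustment for that).
- ROI normalization implements per-ROI Q3 factors and geometric-mean
  background; probe-to-gene collapsing, dispersion modeling and
  differential expression are out of scope.
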