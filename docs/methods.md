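# Methods

## Scope and data model

The pipeline starts from GenePix Results (GPR) spot tables and a GenePix
Array List (GAL) layout — both tab-separated ATF text — not from slide
images; spot segmentation and pixel statistics are the scanner software's
job. A slide carries 4 replicate sub-arrays ("blocks"); every probe appears
once per block, so antigens are measured in quadruplicate. Probe classes
are inferred from probe names (`IgG1`..`IgG6` → dilution-series controls,
`Cy3BSA*` → the constant-concentration BSA control, `BUFFER`/`EMPTY` →
printing buffer, everything else antigen); the prefixes are configurable
because control naming is a lab convention, not part of the format. The
reader accepts either the 532 nm or the 635 nm column pair (default 532,
the Cy3 channel) and never filters rows: flagged spots are carried into the
data model and excluded only at aggregation time.

## QC

Net intensity is foreground minus background, clipped at zero — background
can exceed foreground on weak spots and negative RFUs are not meaningful.
CV% uses the n−1 sample standard deviation; the choice is not dictated by
the CV formula itself and is pinned here (and in tests) for
reproducibility. Replicas are aggregated by the mean over unflagged spots
(median via config); a probe with all four replicas flagged is recorded as
missing rather than erroring, since missingness is a property of the data.

The IgG gate normalizes the six per-level mean net RFUs by the level-1
value, divides by the ideal two-fold series (1/2)^(level−1) (terminal ratio
1/32 = 0.03125), and reports the CV% of the six ratios; the construction
makes it invariant to overall slide brightness. The replicate-spot gate
averages per-probe replica CV% over antigen probes with at least two
unflagged replicas and positive mean. The Cy3-BSA gate is the CV% across
all unflagged Cy3-BSA replicas. All three are gated at 15% by default;
every threshold is a parameter. A study's own observed CV values are
data-dependent and are reported, never asserted.

## Normalization

Only the Cy3-BSA controls enter the quantile step: each column (sample) of
the Cy3-BSA spots × samples matrix is sorted ascending and the row means of
the sorted matrix form the reference profile. The per-sample factor is the
reference total divided by the sample's Cy3-BSA total. Because sorting
preserves column sums, the factor equals mean-of-totals / total — an
algebraic identity the test suite uses as an independent oracle, and the
reason the sort direction is irrelevant to the factor. Factors are applied
multiplicatively to the replicate-aggregated antigen matrix (aggregated
values, not raw spots, since the downstream statistic consumes per-probe
mean RFUs). Flagged Cy3-BSA replicas are excluded and imputed with the
sample's remaining-replica mean; a sample with *all* Cy3-BSA spots flagged
cannot be normalized and is treated as a QC failure. Normalization
equalizes Cy3-BSA totals exactly, conserves their grand total, and is
idempotent (second-pass factors are 1). No log transform is applied
anywhere: the penetrance statistic is ratio-based on RFU.

## Penetrance fold change

Individual FC divides every sample's value by the full control-group mean
for the protein — the same fixed denominator for control samples (no
leave-one-out). Proteins with a zero control mean are unscorable and are
excluded with a report, not an error. Signals with FC < 2 are zeroed
(FC = 2.0 exactly is retained; the frequency definition counts "≥ 2").
"Below 2-fold above the background threshold" admits a second reading — an
absolute floor — so a buffer-spot-derived floor (mean + 2 SD of buffer net
intensities) is implemented as an optional pre-zeroing step, off by
default; the relative 2-fold rule always applies.

The biomarker call requires pfc_case strictly > 2.0 and both freq_case and
freq_diff ≥ ceil(0.10 × n_case). The frequency cut is stated variously as
">10%" and "≥10%" in the field; ≥ with ceiling is used here — for a
9-case cohort both readings give the same integer (1). Ranking is by
descending freq_case, then descending pfc_case, ties alphabetical; applied
to the packaged 23-protein reference summary this reproduces the published
row order exactly. pfc with no penetrant sample is reported as 0 and left
unranked. Whether frequencies are counted before or after zeroing is
immaterial under the default interpretation (both condition on FC ≥ 2);
the implementation counts on the zeroed matrix. By construction pfc_case
≥ 2 whenever freq_case ≥ 1 (a mean of values each ≥ 2× the control mean),
which the suite checks as a property. No significance testing or
multiple-testing correction is applied: the statistic is a thresholded
descriptive score, and treating it as more would overstate it.

## Stratification and annotation

Clustering uses SciPy's Ward linkage on Euclidean distances (the
Lance–Williams "ward" criterion), on both axes of the individual
fold-change matrix restricted to called biomarkers; 3-point linkages are
pinned against hand-computed merge heights in the tests. Heatmap cells are
raw fold changes (a per-protein z-score toggle exists but is off: fold
change is the quantity the analysis defines). Dendrograms are serialized
as newick via scikit-bio. Sub-cohort signatures re-run the full penetrance
pipeline on a case subset against the unchanged controls and report the
overlap partition (overlap / unique-to-subset / unique-to-full) as exact
set sizes. Disease annotation intersects the signature with a pluggable
disease → targets table; the packaged default is the transcribed Open
Targets association table of the reference study. Live database queries
are out of scope.

## Packaged reference tables

The three published tables of the original 12-sample beta-thalassemia-major
study are shipped verbatim. Two transcription artifacts in the per-patient
table are fixed and documented in the module (a duplicated gene symbol
de-duplicated; three run-together symbols split). The per-patient lists
and the 23-protein summary disagree on 14 proteins' frequencies (e.g.
MED22, EPS15 and TRAF1 appear in the summary with frequency 3 but in no
patient's list); the package flags the discordant set and deliberately does
not reconcile the two tables. The reference study's own serum-derived CV
percentages and sub-cohort Venn counts depend on raw arrays that were never
deposited and are therefore not reproduction targets; the printed table
relationships (frequency agreement for the 9 concordant proteins,
fold-change extrema 13.38/2.16, the 4 thalassemia-associated and 19 novel
antigens, all 23 rows satisfying the calling rule) are.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline relies on,
with defaults fixed at the reference study design: 9 cases vs 3 controls,
1600 antigens, quadruplicate spotting, one IgG series replica and four
Cy3-BSA replicas per block, four buffer spots per block.

* **Antigen baselines** are log-normal (log-mean 5.0 ≈ 148 RFU median,
  log-SD 0.8), matching the right-skew of RFU data and the ~85–250 RFU
  control means of the reference signature.
* **Per-sample scale drift** is uniform on (0.7, 1.4) — the multiplicative
  technical effect the Cy3-BSA normalization exists to remove.
* **Planted biomarkers** multiply the baseline by a configurable fold in a
  penetrant subset of cases (the first round(penetrance × n_case) indices
  of a seeded shuffle, recorded in the ground-truth file).
* **Spot noise** is multiplicative Gaussian (CV 10% by default) plus an
  additive background draw (mean 50, SD 10 RFU) written to the spot's
  background column, so noise-free nets recover true levels exactly; the
  true noise process of scanner data is not published, so this is a
  modelling choice, not an emulation.
* **Controls**: IgG levels follow the exact series x(1/2)^(level−1)
  (x = 40 000 RFU, scaled per sample); Cy3-BSA shares one true level
  (20 000 RFU × sample scale).
* Intensities are serialized as rounded integers (scanner convention);
  `round_intensities=False` keeps exact floats so closed-form expectations
  hold to machine precision in tests.

One seeded generator drives everything; a fixed seed gives byte-identical
output files. The generator does **not** emulate spatial artifacts,
scanner saturation, within-spot pixel distributions, or antigen-specific
cross-reactivity — so passing recovery tests demonstrates the statistic's
correctness under the stated noise model, not robustness to every failure
mode of real slides. With 10% spot noise a slide's Cy3-BSA replica CV
occasionally exceeds the 15% gate by chance; the pipeline halts there by
default, with an explicit override to carry flagged slides forward.

## Problem sizes and determinism

Property suites run the full design (1600 probes, 12 samples) over 25 seeds
for parameter recovery — mean sensitivity ≥ 0.9 and null false-positive
rate ≤ 0.02 at fold 5, penetrance 0.5, 10% noise — and smaller 60–200-probe
studies elsewhere; fold-recovery checks use 5 seeds × 5 planted probes per
fold. The factor oracle runs 1000 random matrices. Everything downstream
of the generator is deterministic; the only randomness is the generator's
seed, and hypothesis-based property tests run derandomized.
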