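# immunoarray

Analysis pipeline for protein-microarray autoantibody profiling: quality
control, control-probe-driven normalization, and penetrance fold-change
biomarker calling for GenePix-format array studies, with a seeded synthetic
study generator carrying known ground truth.

## The problem

Serum autoantibodies against self-proteins are candidate prognostic markers
in diseases with abnormal immune reactivity, such as beta-thalassemia major.
A protein microarray (e.g. the Sengenics Immunome design, ~1600 folded human
antigens spotted in quadruplicate across 4 sub-arrays per slide) measures
each serum sample's IgG reactivity as relative fluorescence units (RFU) per
spot. Calling elevated autoantibodies from such data requires three steps
that this package implements as a tested, reusable library:

1. **QC** — three CV% gates per slide, all against a 15% cut-off:
   linearity of a 6-step two-fold IgG dilution control series, replicate-spot
   variability, and variability of the constant-concentration Cy3-BSA
   control. CV% = (n−1 sample SD / mean) × 100.
2. **Normalization** — Cy3-BSA is spotted at constant concentration, so
   between-slide differences in its signal are technical. All Cy3-BSA net
   intensities are loaded into a spots × samples matrix *X*; each column is
   sorted and the row means of the sorted matrix give a quantile reference
   ⟨*X*ᵢ⟩; each sample *k* is scaled by

   *k* = Σ⟨*X*ᵢ⟩ / Σ*X*ₖ,

   which equalizes Cy3-BSA totals across slides.
3. **Penetrance fold change** — autoantibody responses are penetrant in a
   subset of patients, so group means dilute them. Per protein:
   individual FC = H / μ(H_control); signals with FC < 2 are zeroed;
   penetrance frequency = count of samples per group with FC ≥ 2;
   penetrance fold change = mean over penetrant samples / μ(H_control).
   A protein is called a biomarker when pfc_case > 2.0 and both the case
   frequency and the case−control frequency difference reach 10% of the case
   count (ceiling), ranked by descending frequency then fold change.

Downstream, Ward/Euclidean hierarchical clustering of the biomarker
fold-change matrix stratifies samples, sub-cohort signatures are compared by
re-running the pipeline on a case subset, and called biomarkers are
annotated against a packaged disease-association table. The package also
ships, verbatim, the published 12-sample beta-thalassemia study tables
(per-patient biomarker lists, the 23-protein signature, and its disease
associations) as machine-readable reference data.

## Worked example

```python
from immunoarray import run_qc, normalize_study, score_penetrance
from immunoarray.synthetic_data import SyntheticConfig, simulate_study, with_planted

cfg = with_planted(
    SyntheticConfig(n_antigens=200, seed=42), n_planted=3, fold=5.0, penetrance=0.5
)
_, samples, truth = simulate_study(cfg)           # 9 cases vs 3 controls
cases = [s.sample_id for s in samples if s.group == "case"]
controls = [s.sample_id for s in samples if s.group == "control"]

report = run_qc(samples)                          # three CV% gates
print(report.study_means.round(2).to_dict(), "all passed:", report.all_passed)

H, factors = normalize_study(samples)             # Cy3-BSA composite normalization
result = score_penetrance(H, cases, controls)     # penetrance statistic + calling
print(result.biomarkers[["freq_case", "freq_diff", "pfc_case", "mean_control", "rank"]].round(2))
print("planted:", sorted(p.probe_id for p in truth.planted))
```

prints

```
{'igg_dilution_cv': 4.72, 'replicate_spot_cv': 9.34, 'cy3bsa_replica_cv': 9.68} all passed: True
         freq_case  freq_diff  pfc_case  mean_control  rank
protein
AG0003           5          5      5.30        267.55     1
AG0002           5          5      5.09         65.08     2
AG0001           5          5      5.07        186.96     3
planted: ['AG0001', 'AG0002', 'AG0003']
```

The study means show ~5% dilution-series error and ~9–10% replicate noise
(consistent with the generator's 10% spot-noise CV), all under the 15% gate.
The three planted biomarkers — fold 5, penetrant in 5 of 9 cases — are
recovered exactly: frequency 5, estimated penetrance fold change ≈ 5, and no
null probe among the 197 others is called.

## The analysis

Numbered drivers under `analysis/` run the full study end to end, writing
tables under `results/`:

| script | step |
|---|---|
| `01_simulate_study.py` | seeded 9 vs 3 study, 1600 antigens, 20 planted biomarkers |
| `02_quality_control.py` | the three CV% gates per slide |
| `03_normalize.py` | scaling factors + normalized protein × sample matrix |
| `04_call_biomarkers.py` | penetrance table, biomarker calls, recovery vs ground truth |
| `05_stratify.py` | Ward clustering, sub-cohort signature, disease annotation |
| `06_reference_consistency.py` | cross-checks among the packaged published tables |

The same stages are exposed as a CLI
(`immunoarray simulate|qc|normalize|penetrance|cluster|annotate|run`); `run`
executes everything from a YAML config and writes a manifest with input
checksums and per-stage timings.

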