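# cfmulti

Multimodal liquid-biopsy analysis of plasma and urinary cell-free DNA
(cfDNA) for prostate cancer, as a tested Python pipeline with a
synthetic-cohort generator.

Detecting circulating tumor DNA (ctDNA) in newly diagnosed prostate cancer
is hard: tumor fractions in plasma are often below 1–5%, and no single
read-out is sensitive enough on its own. `cfmulti` implements the four
complementary (epi)genomic read-outs used for this problem and integrates
them across two biofluids:

1. **Tumor fraction (TFx)** from low-coverage WGS bin counts: 1000 kb bins
   are GC/mappability-normalized, referenced against a panel of normals
   (PoN), segmented by a hidden Markov model over copy states
   c ∈ {0..4} with emission means μ_c(t) = log2((t·c + 2(1−t))/2), and TFx
   is estimated by likelihood grid search over t ∈ {0, 0.01, …, 0.95}.
   In-silico size selection to 90–150 bp enriches short tumor fragments and
   raises TFx sensitivity in plasma.
2. **Chromosomal instability (CIA) score**: per-bin z-scores against the
   PoN, summarized as Σ_{|z|>3}(|z| − 3) / n_bins.
3. **Methylation score** from methylated-DNA immunoprecipitation
   enrichment in 300 bp windows: nrpkm → β-values in [0, 1], scored as the
   median β over 67 tumor-hypermethylated marker windows derived from a
   tissue-vs-buffy-coat DMR analysis (adjusted p < 0.01, log2FC > 2)
   intersected with an external top-ranked DMR list.
4. **Fragmentation features**: the 10 bp-oscillation score on the
   30–150 bp plasma profile (sum of local-maximum heights minus sum of
   local-minimum depths; lower in tumor samples) and the urinary P163–169
   (proportion of 163–169 bp fragments; higher in tumor samples).

ctDNA positivity is called per feature against control-calibrated
percentile thresholds (95th percentile; 5th for the oscillation score,
strictly beyond the threshold), and plasma/urine calls are integrated
complementarily into a per-patient 0–4 positivity count and an oncoprint.
A statistics layer provides Kruskal–Wallis + Dunn post-hoc tests,
BH correction, logistic models combining PSA with cfDNA features, ROC/AUC,
DeLong comparison, stratified bootstrap, and likelihood-ratio tests.

Because the study's sequencing data are controlled-access, the package
ships a first-class synthetic-cohort generator (`cfmulti.simulate`) that
emulates the data layers with known ground truth — nucleosomal plasma
densities (167/334 bp peaks, 10 bp sub-150 bp oscillation), broad 30–400 bp
urinary densities, copy-number bin counts with GC bias, marker-window
methylation mixtures, and cohort structure (36 controls / 55 localized /
18 advanced, PSA medians ~2 / ~8 / ~19 ng/mL) — so every stage is testable
end to end.

## Worked example

```python
from cfmulti.datatypes import Cohort, FeatureTable
from cfmulti.detection import PercentileDetector, detection_report
from cfmulti.models import discrimination_models
from cfmulti.pipeline import compute_feature_table
from cfmulti.simulate import GeneratorConfig, gen_cohort

config = GeneratorConfig(n_controls=20, n_lpca=20, n_apca=12, n_missing_urine=2,
                         n_bins=800, n_windows=1500, n_fragments=300_000, seed=42)
cohort = gen_cohort(config)
table = compute_feature_table(cohort)           # TFx, CIA, methylation, fragmentation

controls = {r.patient_id for r in cohort.samples if r.cohort == Cohort.CONTROL}
is_ctrl = table.df.index.get_level_values("patient_id").isin(controls)
detector = PercentileDetector().fit(FeatureTable(df=table.df[is_ctrl]))
report = detection_report(detector.predict(table), cohort.sheet())

rates = report["rates"]
print(rates[rates.fluid == "complementary"]
      .pivot(index="family", columns="cohort", values="rate_pct").round(1))

res = discrimination_models(table, cohort.samples, contrast="lpca-vs-apca", seed=42)
print(res["psa_only"]["auc"], res["psa_plus_cfdna"]["auc"], res["lrt"])
```

Output (complementary plasma-or-urine detection rates, %):

```
cohort          aPCa  lPCa
family
any            100.0  75.0
cia            100.0  55.0
fragmentation   66.7   5.0
methylation    100.0  55.0
tfx             91.7  55.0
```

and the model comparison: PSA-only AUC 0.78 vs PSA+cfDNA AUC 0.98
(DeLong p = 0.033; likelihood-ratio χ² = 20.2, df = 5, p = 0.0012).
Read: on this simulated cohort every advanced-disease patient is
ctDNA-positive in at least one analysis, localized disease is detected in
75% of patients only because plasma and urine complement each other, and
adding the five quantitative cfDNA features (cross-fluid max-z TFx, CIA
and methylation score, plasma oscillation score, urinary P163–169)
markedly improves localized-vs-advanced discrimination beyond PSA.

A command-line surface mirrors the library:
`cfmulti simulate | fragment | cnv | methyl | derive-markers | detect | model`.

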