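# Annotated run configuration for `mutatlas run --config <this file>`.
# Every key is optional; values shown are the defaults unless noted.

out_dir: mutatlas_run     # all stage outputs, manifest.json, report.md
seed: 0                   # drives the synthetic generator (generate stage)

# Stages execute in this order; remove entries to skip stages. A skipped
# upstream stage makes downstream stages fail fast unless their inputs are
# provided under `inputs:`.
stages: [generate, merge, stats, mirna, isomir, clinical, report]

thresholds:
  hypermutation: 10000          # exome burden strictly above this excludes a sample
  detectability_pan: 0.30       # max zero-fraction for a miRNA, pan-cancer scope
  detectability_single: 0.10    # ... single-cancer scope
  alpha: 0.05                   # nominal significance for volcano/arm counts
  overmutation_nominal: 0.00005 # per-test cut matching Bonferroni-adjusted 0.05
  min_rpm: 100.0                # isomiR selection: median total RPM of 3p-miRNAs
  hotspot_recurrence: 3         # min mutations per residue to call a hotspot
  pseudocount: 1.0              # RPM pseudocount for log2 ratios

# Group comparisons
focus_gene: DICER1        # gene for the miRNA/isomiR group analyses
focus_class: hotspot      # hotspot | deleterious | missense | ... | any
survival_gene: SMAD4
survival_class: deleterious
cnv_gene: SMAD4

# When the generate stage is disabled, point the pipeline at existing files:
# inputs:
#   calls_dir: /data/calls            # <sample>.<caller>.vcf files
#   regions: /data/regions.bed
#   transcripts: /data/transcripts.json
#   clinical: /data/clinical.tsv
#   expression_normalized: /data/expr_norm.tsv
#   expression_rpm: /data/expr_rpm.tsv
#   mirna_annotations: /data/mirna_annotations.tsv
#   isomirs: /data/isomirs.tsv
#   copy_number: /data/copy_number.tsv

# Synthetic cohort (generate stage). Omit to use the package defaults.
synthetic:
  n_samples_per_cancer: 40
  cancer_types: [PAAD, COAD, READ, UCEC, OV, SKCM]
  hotspot_spec:
    - {gene: SMAD4, residue: 361, count: 12, cancers: [PAAD, COAD, READ]}
    - {gene: DICER1, residue: 1709, count: 6, cancers: [UCEC]}
    - {gene: PRKRA, residue: 127, count: 4, cancers: [OV, COAD]}
  deleterious_rate: 0.04          # per gene, per sample
  background_snv_rate: 0.3        # benign SNVs per sample (Poisson mean)
  noise_call_rate: 1.0            # filter-failing calls per sample per caller
  hypermutated_fraction: 0.01
  arm_effect: {gene: DICER1, mutation_class: hotspot, shift_5p: -0.5, shift_3p: 0.5}
  reference_mirna_id: hsa-miR-451a
  survival_effect: {gene: SMAD4, mutation_class: deleterious, hazard_ratio: 2.0}
  cnv_effect: {gene: SMAD4, del_prob_mutated: 0.6, del_prob_background: 0.1}
  main_fraction_shift: 0.05       # isomiR main-fraction reduction in carriers
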