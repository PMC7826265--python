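# mutatlas

Somatic mutations in the genes that make and operate microRNAs — DROSHA,
DGCR8, DICER1, the Argonautes, SMAD transcription factors, and their
partners — can reshape the miRNA profile of a tumor. `mutatlas` is a
pipeline for characterizing such mutations across a multi-cancer cohort
and tracing their downstream consequences: which genes are overmutated in
which cancers, which residues are recurrent hotspots, how mutation groups
shift miRNA levels (including the tell-tale asymmetry between 5p- and
3p-arm miRNAs produced by RNase-domain lesions in DICER1), whether those
shifts survive re-normalization against a Dicer-independent reference
miRNA (miR-451a), how 5′-isomiR composition changes, and whether carriers
fare worse clinically. It is written for computational cancer biologists
who have per-sample somatic call sets, small-RNA expression matrices, and
clinical tables, and want a tested, reproducible path from raw calls to
these summaries.

## What it computes

* **Consensus calls** — PASS records from four caller dialects (MuSE,
  MuTect2, VarScan2, SomaticSniper) are filtered by four reliability
  criteria — ≥2 tumor alt reads when the normal is clean, tumor/normal
  alt-frequency ratio ≥ 5, somatic score SSC > 30, base quality BQ > 20 —
  merged without duplication, and restricted to coding exons ±2 nt.
  Consequences come from a simplified CDS model (missense / synonymous /
  nonsense / frameshift / in-frame / splice-site / start-stop);
  *deleterious* = {frameshift, nonsense, splice-site}.
* **Cohort statistics** — hypermutated samples (>10,000 exome mutations)
  are excluded; per gene × cancer mutated-sample frequencies; one-sided
  Fisher overmutation tests against the pan-cancer background with
  Bonferroni control; hotspot residues with ≥3 recurrent mutations.
* **miRNA differential analysis** — detectability filtering (≤30% /
  ≤10% zeros), per-cancer normalization to median 0 and range [−1, 1],
  mutated-vs-reference rank-sum tests per miRNA, arm-asymmetry statistics,
  and log-ratio re-normalization against miR-451a,
  x′ = log₂(x+1) − log₂(x_ref+1).
* **isomiR fractions** — for highly expressed 3p-miRNAs (median ≥ 100
  RPM), the share of reads carried by the main 5′ isoform, compared
  between mutation groups.
* **Clinical association** — Kaplan–Meier/log-rank survival with a Cox
  hazard ratio, Cochran–Mantel–Haenszel stage tests stratified by cancer
  type, and co-occurrence with thresholded copy-number deletions.
* **Synthetic cohorts** — a generator that emits every input format with
  planted hotspots, hypermutated samples, arm-asymmetric expression
  shifts sparing the reference miRNA, isomiR shifts, survival hazards and
  deletion enrichment, plus the ground truth to validate against.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the full pipeline end-to-end on a generated cohort (six cancer types,
40 samples each, with a planted 5p-down/3p-up effect in DICER1-hotspot
carriers and a hazard ratio of 2 for SMAD4-deleterious carriers):

```bash
mutatlas run --out-dir demo_run --seed 3
```

which prints the per-stage summary:

```json
{
 "generate": {"planted_mutations": 138, "hypermutated": 2},
 "merge": {"consensus_mutations": 138},
 "stats": {
  "mutations_retained": 129, "samples_retained": 238,
  "hotspots": 3, "significant_overmutation": 0
 },
 "mirna": {
  "n_mirnas_tested": 129, "n_mutated": 6, "n_reference": 216,
  "direction": {"n_significant": 17, "n_down": 8, "n_up": 9,
                "down_pct": 47, "up_pct": 53}
 },
 "isomir": {"n_mirnas_selected": 36, "pooled_p": 2.595e-134},
 "clinical": {
  "logrank_p": 5.99e-11, "hazard_ratio": 8.61,
  "cmh_p": 0.936, "cnv": {"fisher_p": 1.44e-09}
 }
}
```

Reading the numbers: all 138 planted mutations are recovered by the
consensus stage (the generator's noise calls each fail a reliability
filter and are removed); 9 mutations ride along with the 2 hypermutated
samples and drop out of the retained 129. The three detected hotspots are
exactly the planted recurrences. With only 6 DICER1-hotspot carriers at
this cohort size the volcano is underpowered (17 nominally significant
miRNAs, no arm asymmetry yet — at 200 carriers the 5p/3p split is
essentially perfect; see the validation suite), while the pooled isomiR
comparison, survival difference, and SMAD4-deletion co-occurrence are
already unambiguous. The CMH stage test is null, as planted. A complete
run report lands in `demo_run/report.md`, the stage outputs
(`mutations.tsv`, `diff_results.tsv`, `hotspots.tsv`, `survival.json`, …)
beside it, and `manifest.json` records hashes of every output: the same
config and seed reproduce the run bit-for-bit.

Each stage is also available separately (`mutatlas generate | merge |
stats | mirna | isomir | clinical | report`) and as library functions; an
annotated run configuration is in `docs/example_config.yaml`.

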