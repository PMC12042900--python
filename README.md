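# chkit

Clonal hematopoiesis (CHIP) calling and cohort association toolkit:

* **`chkit.variant_filtering`** — the three rule cascades that turn annotated
  somatic variant tables into CHIP / lymphoid-driver calls:
  whole-exome rules `R1`–`R9` (gene panel membership, gnomAD population-AF
  cap with hotspot exemptions, caller PASS label, somatic/germline quality,
  depth and strand support, splice distance, recurrent-frameshift cohort
  frequency) plus a per-sample 5-bp frameshift-cluster collapse (`C1`);
  lymphoid rules add a 2–35% VAF window (`L1`) and a missense evidence
  requirement (`L2`); targeted-panel rules `P1`–`P8` use a 100× depth floor,
  a 1% cohort-frequency cap and a 2–40% VAF window. Per-participant carrier
  profiles carry max-VAF strata (`lt10`/`ge10`) and gene-group flags.
* **`chkit.array_chip`** — SNP-array hotspot CHIP detection from raw
  two-channel intensities: robust (median/MAD, trimmed) reference-cluster
  fitting, robust-z outlier carrier calling with a relative-BAF floor, a
  locus-qualification heuristic (prevalence ratio vs a sequencing reference
  plus univariate age / hematologic-malignancy associations), and
  array-vs-sequencing concordance (sensitivity by VAF bin, BAF-on-VAF OLS).
* **`chkit.association`** — endpoint harmonization from registry codes
  (prevalent/incident, seropositive-dominance serotyping), covariate-adjusted
  logistic models (OR), Cox proportional-hazards models (HR) with
  malignancy-censoring support, Kaplan–Meier / log-rank, Kruskal–Wallis /
  Fisher / chi-squared group tests, DAS28 24-month AUC, and prevalence-by-age
  tables with Wilson CIs. All p-values are two sided; exclusions are logged.
* **`chkit.synthetic_data`** — seeded simulator producing all three input
  kinds (variant tables with per-rule decoys, array intensities, phenotype +
  registry events) with a ground-truth table for every planted fact.
* **`chkit.io` / `chkit.cli`** — TSV/VCF readers, TSV/JSON writers, and the
  `chkit` command with subcommands `simulate`, `filter-wes`,
  `filter-lymphoid`, `filter-panel`, `call-array`, `qualify-loci`,
  `concordance`, `associate`, `report`. Every run writes a `manifest.json`
  (config hash, seed, versions, input checksums). All coordinates are
  1-based inclusive (VCF convention); all outputs are plain text.

## Quick start

```sh
# simulate a cohort, filter it, and call array carriers
chkit simulate --seed 7 --n 5000 --out-dir sim/
chkit filter-wes --variants sim/variants_wes.tsv --panel sim/chip_panel.tsv \
    --n-samples 5000 --out-dir filtered/
chkit call-array --intensities sim/intensities.tsv --out-dir calls/
chkit qualify-loci --calls calls/calls.tsv --loci sim/loci.tsv \
    --phenotypes sim/phenotypes.tsv --out-dir quals/
chkit report --numerator 121 --denominator 10021   # -> 1.2%
```

Python API mirrors the CLI; see module docstrings.

## Variant TSV dialect

One row per biallelic candidate variant with columns:
`sample_id chrom pos ref alt gene consequence caller_label somatic_quality
germline_quality total_depth alt_depth ref_fwd ref_rev alt_fwd alt_rev
gnomad_max_pop_af cosmic_count reported_lchip reported_all
splice_distance_bp protein_change`. Consequence is one of `missense`,
`nonsense`, `frameshift`, `inframe_indel`, `splice`, `synonymous`, `other`.
VCF input is supported via `--dialect vcf` with INFO/FORMAT keys configured
by a field map (defaults in `chkit.io.DEFAULT_VCF_FIELD_MAP`).
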