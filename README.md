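# nddtriage

Variant triage toolkit for neurodevelopmental-disorder (NDD) gene-panel
cohorts. It implements, as a reusable pipeline:

- **SNV/indel filter cascade** (`nddtriage.snv_triage`): virtual-panel
  restriction, depth/VAF quality rules, gnomAD allele-count filter,
  consequence filter with a four-tool splice-score ensemble, and a
  candidate-prioritization step (ClinVar P/LP, gnomAD absence, or predicted
  strong protein effect — LoF, PROVEAN ≤ −2.5 in-frame indels, or a
  deleterious majority among available missense predictors).
- **Re-analysis / mosaic mode**: relaxed VAF bounds (20% LoF / 25% non-LoF in
  the 10–49× depth band; 10% at ≥50×) plus cohort-recurrence artifact
  flagging (gnomAD-absent sites carried by ≥4 samples).
- **Recessive extension**: AF ≥ 0.1% / >4 gnomAD homozygotes filter with
  homozygous and unphased compound-het candidate reporting.
- **Dual-caller CNV consensus** (`nddtriage.cnv_triage`): cohort-recurrence,
  population-SV (DGV/gnomAD-SV) and single-caller quality filters on
  XHMM-like + ExomeDepth-like call tables, with reciprocal-overlap matching
  and Phred-based candidate prioritization.
- **HPO phenotype stratification** (`nddtriage.hpo_phenotype`): ASD vs
  ID/GDD subset classification from literal HPO code sets and 16-category
  phenotype flags.
- **Cohort statistics** (`nddtriage.cohort_stats`): diagnostic yields,
  Table-shaped summaries, Yates-corrected 2×2 χ², uncorrected
  goodness-of-fit χ², ϕ and Glass rank-biserial coefficients.
- **Phenotype profiling** (`nddtriage.profiling`): class-balanced random
  forest (per-tree stratified undersampling, 80% of the minority class),
  OOB votes/metrics/AUC, case proximities, Ward prototype clustering and a
  Mann–Whitney vote comparison.
- **Synthetic cohorts** (`nddtriage.synthetic_cohort`): seeded generator
  with planted pathogenic/mosaic/CNV events, an independent truth table and
  exact analytic expectations for the filter pass rates.

## CLI

```bash
nddtriage simulate --seed 7 --out sim/          # synthetic cohort bundle
nddtriage snv --input sim/variants.tsv --panel sim/panel.bed \
    --genes sim/genes.txt --mode reanalysis --recessive \
    --out decisions.tsv --summary summary.json
nddtriage cnv --calls-a sim/cnv_a.tsv --calls-b sim/cnv_b.tsv \
    --popsv sim/popsv.tsv --out cnv.tsv
nddtriage phenotype --patients sim/patients.tsv --categories sim/categories.tsv \
    --out phenotypes.tsv
nddtriage stats --patients sim/patients.tsv --out stats.json
nddtriage profile --patients sim/patients.tsv --categories sim/categories.tsv \
    --seed 1 --trees 5000 --out profile.json
```

Variant input is either the flat TSV produced by `simulate` (one row per
sample×variant, `pred_<NAME>` columns for the 36 deleteriousness predictors)
or a VCF 4.x file (`--format vcf`); INFO-key names are configurable in
`nddtriage.io.DEFAULT_VCF_MAPPING`. Thresholds can be overridden with a
YAML file passed via `--config` (keys as in
`nddtriage.variant_model.FilterThresholds`).

Decision TSVs use stable snake_case rule identifiers in the `reasons`
column: `not_in_panel`, `no_coverage`, `low_depth`, `low_vaf`,
`low_vaf_lowdp_band`, `low_vaf_mosaic_band`, `gnomad_ac_gt_max`,
`consequence_not_relevant`, `clinvar_plp`, `gnomad_absent`, `strong_effect`,
`no_priority_route`, `recurrent_in_cohort`.

## Conventions

- VAF = alt reads / total site depth; undefined at zero depth.
- Internal coordinates are half-open 0-based; VCF positions 1-based; BED
  input 0-based half-open. "Absent in gnomAD" means no record or AC = 0.
- Priority routes combine as *any* by default (`priority_mode:
  conjunction` requires all three).
- Depth exactly 50 falls in the ≥50× mosaic band of re-analysis mode.
- The artifact flag is advisory: statuses are not changed.
- The built-in HPO category map only covers the literal subset-defining
  codes (approximate assignments); supply a full `code → category` TSV for
  real cohorts.

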