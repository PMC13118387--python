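# biomeshare

Statistical analysis of paired oral (saliva) and gastric (biopsy)
shotgun-metagenomic taxonomic profiles from a case–control cohort:
alpha-diversity, Bray–Curtis ordination, per-taxon group association, and a
per-subject oral→gastric taxa-sharing procedure, together with a seeded
synthetic paired-cohort generator for recovery and calibration experiments.

The pipeline starts from classified-read count tables (taxa × samples, TSV)
and a sample metadata table (sample, subject, compartment ∈ {saliva, biopsy},
group ∈ {case, control}); everything upstream (sequencing, QC, taxonomic
classification) is out of scope.

## Modules

| module | what it does |
| --- | --- |
| `biomeshare.profiles_io` | count-table / metadata TSV I/O, validation, saliva↔biopsy subject pairing |
| `biomeshare.filtering_stats` | prevalence filtering, read totals, descriptives, bootstrap-supported Welch t-tests, post hoc power (noncentral t, pooled SD) |
| `biomeshare.diversity` | Shannon–Wiener index (nats by default) and per-compartment group comparison |
| `biomeshare.beta_diversity` | Bray–Curtis distances on relative abundances, classical-scaling PCoA, PERMANOVA-style permutation test |
| `biomeshare.association` | per-taxon Spearman (midrank ties) group association with BH-FDR; for binary presence this equals the phi coefficient |
| `biomeshare.sharing` | per-subject intersection of saliva and biopsy presence sets; group summaries, exclusivity flags, k-distributions, co-sharing patterns |
| `biomeshare.synthetic` | seeded log-normal/multinomial paired-cohort generator with translocator seeding and ground-truth bookkeeping |
| `biomeshare.cli` | config-driven orchestration and the `biomeshare` command |

## CLI

```sh
# generate a synthetic paired cohort (counts.tsv, metadata.tsv, truth sidecars)
biomeshare generate --seed 1 --outdir cohort/

# run the full analysis on any count table + metadata
biomeshare analyze --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --outdir analysis/ --seed 1

# generate + analyze + score translocator recovery in one go
biomeshare all --seed 1 --transloc-prob 1.0 --pool-overlap 0 --outdir run/

# recovery scoring only
biomeshare evaluate --seed 1 --outdir recovery/
```

`analyze` accepts a YAML config (`--config`) holding any field of
`biomeshare.cli.RunConfig` (presence threshold, prevalence cutoff, Shannon
log base, bootstrap/permutation counts, association mode, top-N for the
sharing table, seed, …). The config is echoed verbatim into the output
directory along with a `manifest.json` (versions, seed, config hash), and
every random procedure takes its seed from the config, so a run is a pure
function of (inputs, config, seed).

Outputs are tidy TSVs: per-sample diversity, abundance descriptives,
Bray–Curtis matrices, PCoA coordinates, association tables (case view and
mirrored control view with rho / p / BH-q), the top-N sharing summary with
"Only CA"/"Only CO" exclusivity flags, per-group k-distributions, a
per-subject shared-set table, and a short `summary.md`.

## Notes on conventions

- Counts are absolute classified reads; relative abundances are derived on
  demand and never stored.
- Prevalence of a taxon = fraction of samples with ≥ 1 read (threshold
  configurable); at 40 samples a 2.5% cutoff means detection in ≥ 1 sample.
- The t-test default is Welch; Mann–Whitney U is reported alongside.
  Bootstrap CIs use stratified within-group resampling (B = 1000).
- PCoA discards (and counts) negative eigenvalues; no Cailliez/Lingoes
  correction.
- The group-separation p-value is a PERMANOVA pseudo-F permutation p,
  `(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`.
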