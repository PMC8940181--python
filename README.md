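# tcrgwas

Association mapping between SNP genotypes and T-cell receptor (TCR)
V(D)J recombination statistics, packaged as a tested, reusable pipeline:

- **io_formats** — genotype tables / VCF 4.2, AIRR Rearrangement TSV,
  germline FASTA; MAF, repertoire-size, orphan-gene and
  unidentifiable-D data-preparation filters.
- **vdj_annotation** — most-parsimonious (fewest-N-insertion) V(D)J
  recombination scenarios per read: trims, insertion strings,
  P-nucleotides, frame/stop productivity, and gene-allele grouping.
- **repertoire_features** — per-subject means (simple model) and
  per-(subject × gene-allele-group) weighted means with
  W_im = N_im / Σ_m N_im (gene-conditioned model), untrimmed-P
  fractions, TRBD2 genotype calling, TRBJ1 restriction.
- **association** — OLS / weighted fixed-effects fits with PC
  covariates, T = β̂₁/se tested against N(0,1), clustered bootstrap
  (subjects as sampling unit, 100 reps, 5×10⁻⁵ trigger), TRBD2-corrected
  model, stepwise conditional scans, genome scans.
- **popstruct** — frequency-scaled genotype PCA, labeled-anchor cluster
  assignment, genomic inflation λ = median(T²)/0.456 with the λ<1.03
  rule and 10,000-SNP subsample mode, Bonferroni thresholds, per-cluster
  feature/MAF t-tests.
- **synthetic** — cohort generator with cluster-structured allele
  frequencies and planted usage / trimming / insertion effects plus full
  ground truth, so every stage is testable offline.
- **pipeline / cli** — `tcrgwas` entry point orchestrating
  prepare → annotate → condense → scan → diagnostics from one YAML
  config, deterministic under a seed.

## CLI

```bash
tcrgwas simulate --preset desk --seed 1 --out cohort/
tcrgwas prepare  --genotypes cohort/genotypes.tsv \
                 --repertoire-dir cohort/repertoires \
                 --germline cohort/germline.fasta --min-maf 0.05 --out prep/
tcrgwas annotate --germline cohort/germline.fasta \
                 --in cohort/repertoires/S0000.tsv --out annotated.tsv
tcrgwas condense --repertoire-dir annotated/ --feature v_trim \
                 --model gene_conditioned --productivity non_productive \
                 --out condensed.tsv
tcrgwas threshold --subtypes 76 --productivities 2 --snps 6456824
tcrgwas conditional --genotypes prep/genotypes.filtered.tsv \
                    --condensed condensed.tsv --locus chr1:100000-200000 \
                    --threshold 1e-5
tcrgwas diagnostics --results run/associations.tsv
tcrgwas run --config run.yaml --out run/
```

A minimal `run.yaml`:

```yaml
simulate_preset: desk
seed: 1
features: ["usage:TRBV05", "v_trim", "n_total"]
repertoire_log10_min: {productive: 2.5, non_productive: 2.0}
```

All analysis constants (MAF 0.05, 8 PCs, 100 bootstrap reps, 5e-5
trigger, 200 kb locus window, λ threshold 1.03, χ²₁ median 0.456,
10,000-SNP subsample) are surfaced in `RunConfig` and overridable.

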