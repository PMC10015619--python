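# asekit

Analysis toolkit for allele-specific expression (ASE) in F1 hybrids between
two diverged populations (here labelled *marine* and *freshwater*). Starting
from gene-level allelic read counts across tissues, timepoints and
replicates, the pipeline provides:

- **ASE calling** — per-tissue exact binomial (or beta-binomial) tests of the
  marine read fraction against 0.5 on replicate-pooled counts, with
  Benjamini–Hochberg correction per tissue-timepoint, plus site-level
  mapping-bias filters (zero-allele sites, |log2 ratio| > 10).
- **Multi-tissue heterogeneity classification** — Bayesian model comparison
  over per-tissue states *no / moderate / strong ASE* with Beta-mixture
  priors (Beta(2000,2000); ½Beta(80,36)+½Beta(36,80); ½Beta(80,7)+½Beta(7,80)),
  yielding posterior probabilities for NOASE / UNIFORM_ASE / HET0 / HET1
  classes and tissue-specific ASE.
- **Developmental differential ASE** — Fisher's exact tests comparing allelic
  ratios between two developmental timepoints, with early/late-bias and
  timepoint-specific vs magnitude-change classification.
- **Sign test for lineage-specific selection** — per gene-set directional
  bias (Fisher's exact against the direction-assigned background), a
  10,000-fold gene-to-set shuffling permutation p-value, Fisher's-method
  combination across tissues, and a dual-criterion report.
- **Genomic enrichment** — per-gene divergence-score (CSS Z) annotation, SNP
  density binning, within-bin label-shuffling permutation tests, and
  SNP-density-matched resampling for EcoPeak and per-chromosome enrichment
  of ASE genes.
- **Synthetic data** — a generator for complete experiments (counts, sites,
  genome with CSS windows / peaks / QTL, direction-biased gene sets) with
  known ground truth, used throughout the test suite.

## Command line

All stages are subcommands of a single `asekit` entry point:

```sh
asekit simulate --out-dir data --seed 1            # synthetic experiment
asekit ase-call --counts data/allelic_counts.tsv --out-prefix out/ase
asekit heterogeneity --counts data/allelic_counts.tsv --out-prefix out/het
asekit dev-ase --counts data/allelic_counts.tsv \
    --ase-results out/ase.ase_results.tsv --out-prefix out/dev
asekit sign-test --ase-results out/ase.ase_results.tsv \
    --sets data/gene_sets.tsv --unit VTP@2,DTP@2,mandible@2 \
    --out-prefix out/sign
asekit enrichment --genes data/genes.bed --css data/css_windows.bed \
    --ecopeaks data/ecopeaks.bed --qtl data/qtl.bed \
    --sites data/site_counts.tsv --ase-results out/ase.ase_results.tsv \
    --out-prefix out/enr
```

`asekit run-all --config config.yaml --out-dir results` chains every stage
from one YAML config (with either a `simulate:` section or an `inputs:`
section pointing at existing files) and writes a deterministic
`manifest.json`. Analysis units are named `tissue@timepoint` (timepoint 1 =
early, 2 = late).

Exit codes: 0 ok, 1 user error (bad inputs/config), 2 internal error.

## File formats

- allelic counts: TSV `gene_id tissue timepoint replicate marine_count
  freshwater_count`
- site counts: TSV `chrom pos gene_id marine_count freshwater_count`
  (1-based positions)
- genes, CSS windows, EcoPeaks, QTL: BED3+ (0-based half-open; column 4 name,
  column 5 score = CSS Z where applicable)
- gene sets and ortholog maps: two-column TSV

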