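# gwaskit

A post-GWAS statistical toolkit for dosage-based association studies, with a
synthetic-cohort simulator so that every analysis stage is testable without
access-controlled genotype data.

## What it does

- **`gwaskit.simcohort`** — haplotype panels with block LD (Gaussian-copula
  AR(1) within blocks), case-control cohorts and ascertained affected-child
  trios under a multiplicative-risk logistic disease model (intercept solved
  from a target prevalence), liability-threshold cohorts with a known
  genetic variance, imputation-style dosage degradation to a target info
  score, and annotation tracks with controllable enrichment around
  associated variants.
- **`gwaskit.gwasio`** — dosage VCF (FORMAT/DS with GT fallback), BED3+,
  recombination-map and association-table readers/writers; variant-level
  imputation QC (info score, reference-subset MAF) and hard-call QC (call
  rate, MAF, exact HWE on controls, differential-missingness Fisher test).
- **`gwaskit.assoc`** — per-variant logistic dosage association (batched
  Newton solver, Wald tests, conditioning, collinearity/separation
  flagging), a family-based dosage transmission test that reduces exactly
  to the classical TDT on hard genotypes, the Cochran-Armitage trend test,
  weighted Z-score combination, inverse-variance fixed-effect
  meta-analysis, and the genomic inflation factor.
- **`gwaskit.finemap`** — ±0.1 cM intervals on a cumulative recombination
  map, approximate Bayes factors (normal prior on the log relative risk,
  default prior SD 0.2), sum-normalized posteriors, minimal 95%/99%
  credible sets, and conditioning-based refinement for multiple
  independent signals.
- **`gwaskit.crmenrich`** — combinatorial cis-regulatory-module maps from
  peak tracks (p300/TFAP2A bound with H3K27ac within 1 kb; plus
  H3K27ac∩H3K4me1 "primed" regions) and a one-sided trend test for
  enrichment of small association P-values inside annotated regions, using
  a 9-category log10 binning or a nominal 0.05 split.
- **`gwaskit.prs`** — polygenic score construction (P-value thresholding,
  greedy LD pruning at r² < 0.25, MAF/info filters), scoring with allele
  orientation, matched (pseudo-control conditional-logistic) and unmatched
  association tests with Nagelkerke pseudo-R², the transmitted vs
  non-transmitted weighted trio score, and variance explained by a fixed
  locus panel with liability-scale estimation.

## CLI

All functionality is exposed through one entry point:

```bash
gwaskit simulate --config scenario.json --out-dir sim/   # synthetic cohorts
gwaskit qc --vcf cohort.vcf --samples samples.tsv --out filtered.vcf
gwaskit assoc --vcf filtered.vcf --samples samples.tsv --out assoc.tsv
gwaskit trio-assoc --child-vcf c.vcf --father-vcf f.vcf --mother-vcf m.vcf --out trio.tsv
gwaskit meta a.tsv b.tsv --method fixed --out meta.tsv
gwaskit credset --assoc assoc.tsv --map recomb_map.tsv --index var5 --out credset.tsv
gwaskit crm --p300 p300.bed --tfap2a tfap2a.bed --k27ac k27ac.bed --k4me1 k4me1.bed \
    --out-active active.bed --out-active-primed both.bed
gwaskit enrich --assoc assoc.tsv --track active.bed --scheme groups
gwaskit prs-build --discovery assoc.tsv --pt 0.2 --prune --ld-vcf panel.vcf --out model.tsv
gwaskit prs-score --model model.tsv --vcf target.vcf --out scores.tsv
gwaskit prs-test --scores scores.tsv --samples samples.tsv
gwaskit trio-score --panel panel.tsv --child-vcf c.vcf --father-vcf f.vcf --mother-vcf m.vcf
```

The `simulate` config is a JSON file; see `tests/test_cli.py` for working
examples of both the case-control and trio scenarios.

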