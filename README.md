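# kovariome

Post-genotyping analysis of a cohort variome — the complete set of small
variants observed in a sequenced cohort — as a tested, configuration-driven
Python pipeline. It is aimed at population-genetics and genome–phenome
analysts who have multi-sample genotype calls (VCF with GT and AD fields)
and a clinical trait table, and who want the standard downstream stack in
one place:

* **Variome QC** — per-sample missingness and het/hom-ratio filters,
  PLINK-style method-of-moments IBD kinship (PI_HAT) with greedy
  unrelated-set selection, PCA-based structure checks, Hardy–Weinberg exact
  tests, and an **allele-balance batch-effect filter**: the mean fraction of
  alternate-supporting reads at heterozygous calls is computed per variant,
  and variants whose mean falls outside the genome-wide mean ± 1 SD are
  excluded as likely sequencing-batch artifacts.
* **Allele-frequency profiling** — classification of variants into
  singleton / doubleton / very rare (AC > 2, AF ≤ 0.001) / rare
  (0.001 < AF ≤ 0.01) / common (0.01 < AF ≤ 0.05) / very common
  (AF > 0.05), novelty annotation against a known-sites list, and
  variant-discovery saturation curves over random sample orderings.
* **Population specificity** — 2×2 Pearson χ² allele-count tests of a target
  cohort against a panel of reference populations; a variant is
  population-specific when P < 5×10⁻⁵ against *every* reference.
* **WGWAS** — per-variant linear/logistic regression of traits on allele
  dosage with sex, age, age², BMI and principal-component covariates,
  genomic-inflation diagnostics (λ_median), greedy index-first LD clumping
  (r² > 0.1 within 250 kb), and Benjamini–Hochberg FDR.
* **Phenomics** — Pearson phenotypic correlations with Fisher-z CIs;
  pleiotropy via the **Variant-Sharing Index**
  `VSI(i,j) = 100·|S_i ∩ S_j| / |S_i ∪ S_j|` over suggestive-association
  variant sets (P < 10⁻⁵); GREML heritability and bivariate genetic
  correlation (`y = Xβ + g + e`, `g ~ N(0, A·σ²_g)` with the genetic
  relationship matrix A) fitted by REML on the GRM eigenbasis, with the
  analytic power formula `power = Φ(h²/SE − z_crit)`,
  `SE = √(2/(N²·var_A))`; and consensus two-sample Mendelian randomization
  (IVW, MR-Egger, MR-PRESSO; a causal call needs FDR < 0.05 in ≥ 2 of 3
  methods) with a multi-edge trait-network export.
* **Imputation evaluation** — squared Pearson correlation between true
  genotypes and imputed dosages, aggregated by alternate-allele-frequency
  bin.
* **Synthetic cohort generator** — Balding–Nichols subpopulation structure,
  Mendelian relatives, batch-biased read counts at heterozygous sites, and
  traits with prescribed heritability / genetic correlation / causal
  effects, with full ground-truth tables for parameter-recovery testing.

## Worked example

```python
import numpy as np
from kovariome.synthetic import CohortConfig, simulate_genotypes, simulate_read_counts
from kovariome.qc import compute_allele_balance, filter_batch_effect
from kovariome.phenomics import compute_vsi
from kovariome.greml import greml_power

cfg = CohortConfig(n_samples=500, n_variants=2000,
                   batch_biased_fraction=0.05, batch_bias_ab=0.65,
                   mean_depth=30.0, seed=11)
genotypes, truth = simulate_genotypes(cfg)
read_counts, rc_truth = simulate_read_counts(genotypes, cfg)

stats = compute_allele_balance(genotypes, read_counts)
keep = filter_batch_effect(stats)
biased = rc_truth["biased_variants"]
print(f"genome-wide mean AB = {stats.genomewide_mean:.4f}, SD = {stats.genomewide_sd:.4f}")
print(f"excluded {np.sum(~keep)} of {len(keep)} variants")
print(f"recovered {np.mean(~keep[biased]):.1%} of the {len(biased)} biased variants")

rec = compute_vsi(638, 632, 569, "D_bilirubin", "T_bilirubin")
print(f"VSI(D_bilirubin, T_bilirubin) = {rec.vsi} (union = {rec.total})")
print(f"GREML power at n=2685, h2=0.3: {greml_power(2685, 0.3):.2f}")
```

prints

```
genome-wide mean AB = 0.5040, SD = 0.0182
excluded 148 of 2000 variants
recovered 100.0% of the 100 biased variants
VSI(D_bilirubin, T_bilirubin) = 81.2 (union = 701)
GREML power at n=2685, h2=0.3: 0.72
```

The allele-balance statistic centres on 0.5 (both alleles equally
supported at true heterozygous calls); the ±1 SD rule removes all 100
variants whose heterozygous allele balance was shifted to 0.65 in one
sequencing batch, at the cost of the expected ~2.5% two-tailed loss of
clean variants. The VSI of 81.2% says the two bilirubin measures share
most of their suggestively associated variants — near-complete pleiotropy
— and the power value says a cohort of 2,685 phenotyped samples detects a
trait with h² = 0.3 about 72% of the time.

## Command line

Every stage is exposed as a subcommand of `kovariome`:

```
kovariome simulate | qc-samples | qc-variants | kinship | pca | profile |
          saturation | pop-specific | gwas | pc | pleiotropy | h2 | rg |
          mr | impute-eval | network | run | greml-power
```

`kovariome run --config pipeline.yaml --seed 1 --out-dir out/` executes the
configured stages in order (QC → profiling → WGWAS → phenomics) and writes
a manifest recording every threshold, seed and per-stage record count.

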