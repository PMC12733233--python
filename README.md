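# mmpassoc

Candidate-gene case–control association toolkit for a three-SNP matrix
metalloproteinase (MMP) panel and anterior cruciate ligament (ACL) injury
phenotypes: **MMP1** rs1799750 (promoter ins/del, alleles D/I), **MMP10**
rs486055 (C/T) and **MMP12** rs2276109 (A/G), studied in a cohort of 160
injured football players and 136 uninjured controls with binary injury
sub-phenotypes (ACLF injury frequency, ACLS strain, ACLRP partial rupture,
ACLRC complete rupture).

The individual-level data behind such studies are typically not public, so
the package pairs every analysis stage with a synthetic-cohort generator
that reproduces the study's statistical structure (group sizes, control
allele frequencies, Hardy–Weinberg genotypes, covariate moments, subtype
prevalences, plantable genetic effects), and it can recompute the published
summary quantities directly from the published count tables.

## What it computes

* **Single-locus scans** (`mmpassoc.assoc`) — genotype codes 1/2/3
  (homozygous major / heterozygous / homozygous minor) are collapsed under
  the codominant, dominant, recessive, overdominant and log-additive
  inheritance models. Odds ratios use the cross-product ratio with the Woolf
  interval, `exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`; p-values come from the
  likelihood-ratio (G) test, with covariate-adjusted logistic fits as an
  alternative estimator; Benjamini–Hochberg FDR is applied within declared
  test families.
* **Hardy–Weinberg tests** — an exact test by full enumeration of
  heterozygote counts conditional on the allele counts, alongside the 1-df
  chi-square test.
* **EM haplotype analysis** (`mmpassoc.haplo`) — maximum-likelihood
  haplotype frequencies under phase ambiguity, and a haplotype-dose logistic
  GLM whose design rows are expanded over compatible phase pairs with
  posterior weights; Wald variances come from the observed-data (mixture)
  information.
* **Logic regression** (`mmpassoc.logicreg`) — each SNP becomes two binary
  dummies (`SNP_1` = carries a minor allele, `SNP_2` = homozygous minor);
  AND/OR trees over these are fitted by simulated annealing, bagged, and
  decomposed into prime implicants whose proportion and out-of-bag
  importance are compared against a freshly-permuted-label null.
* **Power / minimal detectable odds ratio** (`mmpassoc.power`) — analytic
  power of the 1-df score test under HWE genotype frequencies at the control
  minor-allele frequency, and the smallest odds ratio on a grid reaching a
  target power (MDOR).

## Worked example

```python
import mmpassoc as m
from mmpassoc import study
from mmpassoc.assoc import crude_model_scan

# Within-case ACLF table for MMP1 rs1799750: genotype counts
# (D/D, I/D, I/I) of 101 single-injury vs 58 multiple-injury cases
counts = study.WITHIN_CASE_COUNTS["rs1799750"]["ACLF"]   # ((33,58,10),(15,23,20))
est = crude_model_scan(counts, "recessive")[0]
print(f"OR {est.or_:.2f} (95% CI {est.ci_low:.2f}; {est.ci_high:.2f}), p={est.p:.4f}")
# OR 4.79 (95% CI 2.05; 11.19), p=0.0002

res = m.hwe_test(study.CASE_GENOTYPE_COUNTS["rs2276109"])  # (128, 28, 4)
print(f"exact HWE p = {res.p_exact:.3f}, chi-square p = {res.p_chisq:.3f}")
# exact HWE p = 0.115, chi-square p = 0.118
```

Under the recessive model, I/I carriers have 4.79 times the odds of multiple
ACL injuries relative to D/D + I/D carriers, and the case-group rs2276109
genotypes are consistent with Hardy–Weinberg equilibrium.

A full synthetic pipeline from the shell:

```sh
mmpassoc simulate --seed 1 --out sim/
mmpassoc scan --genotypes sim/genotypes.tsv --phenotypes sim/phenotypes.tsv \
         --outcomes status,ACLF --out scan/
mmpassoc hwe --genotypes sim/genotypes.tsv
mmpassoc power --target-power 0.8
```

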