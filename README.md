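# mrkit

Two-sample Mendelian randomization (MR) on GWAS summary statistics, built
for analyses of the kind that link serum lipid levels to disease risk —
e.g. triglycerides and endometriosis — across ancestries: instrument
selection and harmonization, a battery of univariable causal estimators,
pleiotropy and heterogeneity diagnostics, multivariable MR with mediation
decomposition, drug-target (cis-instrument) MR, Bayesian colocalization,
replication meta-analysis, FDR control and power — plus a synthetic
summary-statistics generator with known causal truth so the entire
pipeline can be exercised and calibrated offline.

## Who it is for

Genetic epidemiologists running two-sample MR from published GWAS summary
files (GWAS-SSF-style TSV) who want a scriptable, reproducible pipeline
with explicit bookkeeping at every filtering step, and method developers
who need a generator of paired exposure/outcome (and mediator) summary
statistics with controlled pleiotropy, LD and mediation structure.

## The model

For SNP *j*, let β̂ˣⱼ (se σˣⱼ) be its association with the exposure and
β̂ʸⱼ (se σʸⱼ) with the outcome, harmonized to one effect allele. Under
the instrumental-variable assumptions each Wald ratio ρⱼ = β̂ʸⱼ/β̂ˣⱼ
estimates the causal effect θ. The primary estimator is multiplicative
random-effects IVW,

θ̂ = Σⱼ wⱼρⱼ / Σⱼ wⱼ,  wⱼ = (β̂ˣⱼ)²/(σʸⱼ)²,

with the fixed-effect standard error inflated by max(1, √(Q/(J−1))) where
Q is Cochran's heterogeneity statistic. Pleiotropy-robust complements:
MR-Egger (weighted regression with an intercept estimating directional
pleiotropy), the weighted median (consistent while valid instruments
carry >50% of weight), and constrained maximum likelihood (cML) with BIC
selection of the number of invalid instruments. Instrument quality is
enforced by genome-wide significance (P < 5×10⁻⁸), LD clumping
(r² < 0.001 within 10,000 kb), instrument strength
F = (n−k−1)/k · R²/(1−R²) ≥ 10 with R² = 2·MAF(1−MAF)β², and Steiger
directionality filtering. MR-PRESSO detects outlier instruments by
simulation; multivariable MR regresses outcome betas jointly on several
exposures to give direct effects, from which mediation is decomposed as
indirect = total − direct with proportion mediated indirect/total.
Colocalization uses Wakefield approximate Bayes factors under a
single-causal-variant model (PP.H4 > 0.8 ⇒ shared variant); replication
datasets are pooled by inverse-variance meta-analysis (fixed-effect when
I² < 50%, DerSimonian–Laird otherwise) with Benjamini–Hochberg FDR across
the testing family.

## Worked example

Simulate a study pair with a true causal log-OR of 0.15 from 25
instruments, then run the full univariable analysis:

```sh
mrkit simulate --seed 3 --out-dir sim --n-snp 25 --theta 0.15
mrkit uvmr --exposure sim/exposure.tsv --outcome sim/outcome.tsv --ld sim/ld.tsv
```

which prints (abridged):

```json
{
 "counts": {"candidates_selected": 24, "harmonized": 24,
            "steiger_kept": 24, "f_kept": 24},
 "estimates": {
  "ivw_mre":         {"beta": 0.1504, "se": 0.0058, "or": 1.1623,
                      "ci_low": 1.1492, "ci_high": 1.1756, "n_snp": 24,
                      "q": 29.18, "overdispersion": 1.126},
  "egger":           {"beta": 0.1494, "se": 0.0130, "egger_intercept": 0.00012,
                      "egger_intercept_p": 0.927},
  "weighted_median": {"beta": 0.1510, "se": 0.0074},
  "cml":             {"beta": 0.1505, "se": 0.0052, "cml_k_invalid": 0}
 }
}
```

(values abridged to 4 significant figures). 24 of the 25 simulated SNPs
reach genome-wide significance and survive
clumping and filtering; every estimator's 95% CI covers the generating
effect 0.15, and cML selects zero invalid instruments — what a clean,
pleiotropy-free instrument set should look like. Published results can be
pooled directly: a TSV of odds ratios with CIs fed to `mrkit meta`
returns the fixed-effect pooled OR with its I² model choice, and
`mrkit mediate --total 0.089 --total-se 0.0398 --direct 0.082
--direct-se 0.0401` prints the indirect effect 0.007 with its
delta-method proportion mediated.

The same operations are available as a library (`mrkit.ivw`,
`mrkit.mr_presso`, `mrkit.coloc_abf`, `mrkit.meta_analyze`, ...) and as a
configured pipeline (`mrkit run --config run.yaml`) that writes one TSV
or JSON per stage plus a manifest recording seeds, versions and SNP
counts in/out at every filter.

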