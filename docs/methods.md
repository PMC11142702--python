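# Methods

This note documents the statistical model behind each component, the
defaults and why they were chosen, the design decisions taken where the
methodology is genuinely open, and what the synthetic-data experiments
do and do not establish.

## Two-sample MR model and assumptions

All estimators operate on summary statistics only: per-SNP effect sizes
and standard errors from one GWAS of the exposure and an independent GWAS
of the outcome, harmonized to a shared effect allele. The identifying
assumptions are the usual instrumental-variable triple — relevance
(instrument associated with the exposure), exchangeability (no
confounding of the instrument–outcome relation), and exclusion (no effect
on the outcome except through the exposure). Violations of exclusion
(horizontal pleiotropy) are the central practical threat and motivate the
estimator battery and the diagnostics.

Binary outcomes are treated on the log-odds scale throughout: outcome
betas are log-ORs, causal estimates are reported as OR with a 95% normal
interval using the multiplier 1.959964 everywhere.

## Instrument processing

Pipeline order: genome-wide significance (P < 5×10⁻⁸) → greedy LD
clumping (keep the smallest p; remove candidates within 10,000 kb on the
same chromosome with r² ≥ 0.001; ties broken by chromosome then position
for determinism) → allele harmonization (with optional LD-proxy
substitution, r² > 0.8, disabled by default for fully offline runs) →
Steiger directionality filter → instrument-strength filter F ≥ 10. The
order is recorded in the run manifest; F/Steiger after harmonization was
chosen because both need the paired records, and SNP counts in/out are
conserved (in = kept + dropped) at every step.

Harmonization conventions: swapped allele codings negate the outcome beta
and reflect its allele frequency; strand-complement codings are
re-labelled first. Palindromic SNPs (A/T, C/G) carry no strand
information in their allele labels, so orientation is inferred from
allele frequencies when both are available and both lie outside the
ambiguity zone |EAF − 0.5| ≤ 0.08 (a common community default);
otherwise the SNP is dropped with a recorded reason. Indels and
multi-allelic variants are rejected at parse time — instruments here are
biallelic SNPs.

Steiger filtering drops a SNP when its outcome variance explained exceeds
its exposure variance explained. The per-trait r² is computed from the
association z-score, r² = F/(F + n − 2) with F = (β/σ)², which needs no
allele frequency and treats both traits symmetrically; the
2·MAF(1−MAF)β² form is available when frequencies exist on both sides.
Ties are retained (the filter removes only *stronger* outcome
correlation). A Fisher-z test p-value for the comparison is reported but
deliberately not used to filter: the filter is a deterministic
directionality rule, the p-value is context.

Instrument strength uses the single-SNP F-statistic
F = ((n−k−1)/k)·(R²/(1−R²)) with k = 1 and R² = 2·MAF(1−MAF)β²; per-row
sample sizes are taken as provided in the input file (no effective-N
conversion is applied for binary traits — the convention is the
caller's).

## Univariable estimators

* **Wald ratio** (single SNP): ρ = β̂ʸ/β̂ˣ with first-order se σʸ/|β̂ˣ|.
* **IVW, multiplicative random effects** (primary): weighted
  through-origin regression of outcome on exposure betas, weights 1/σʸ².
  The regression form is used (identical point estimate to the
  ratio-weight form); the fixed-effect se is multiplied by
  max(1, √(Q/(J−1))), so heterogeneity can only widen intervals — the
  scale never shrinks below 1.
* **MR-Egger**: same regression with an intercept. Exposure betas are
  oriented non-negative (outcome co-flipped) before fitting, the standard
  convention making the intercept an estimate of average directional
  pleiotropy; overdispersion floor as above on J−2 df. A design in which
  all oriented exposure betas are equal is collinear with the intercept
  and rejected as degenerate.
* **Weighted median**: Wald ratios ordered, weighted empirical CDF
  (cumulative weight minus half the SNP's own weight) interpolated at
  0.5, ratio-form weights. The standard error is a seeded parametric
  bootstrap (1,000 draws by default) redrawing per-SNP betas from their
  sampling normals — a bootstrap se because no closed form exists.
* **cML**: constrained maximum likelihood with a free pleiotropy
  parameter on exactly K instruments. For fixed K, coordinate ascent:
  given θ the K invalid SNPs are those with the largest standardized
  residuals (βʸ−θβˣ)²/(σʸ²+θ²σˣ²), the valid SNPs' true exposure effects
  have a closed-form update, and θ is re-estimated from the valid set;
  convergence tolerance 1e-8, at most 200 iterations. K is selected by
  BIC with effective n = min(n_exposure, n_outcome); the se comes from
  the observed information with nuisance effects profiled out (arrowhead
  Schur complement). Model selection (not averaging) is the default; K
  ranges over 0…J−3 unless capped.

Dispatch: J = 1 gives the Wald ratio alone; J = 2 adds IVW; J ≥ 3 runs
everything.

## Sensitivity diagnostics

Cochran's Q about the IVW fit with I² = max(0, (Q−df)/Q); the Egger
intercept test (p < 0.05 flags directional pleiotropy — reported, never
used to auto-select a model); leave-one-out IVW re-fits exported as a
plot-ready table; and MR-PRESSO. The PRESSO global statistic is the
residual sum of squares of the leave-one-out IVW fits; its null
distribution comes from parametric simulation under the fitted model
(default 1,000 draws, seeded, bit-reproducible). The global p carries
+1/(n+1) smoothing; per-SNP outlier p-values are plain empirical
proportions — with the smoothed estimator a residual more extreme than
every simulation could never clear the Bonferroni bar at realistic
instrument counts — Bonferroni-adjusted across SNPs, and flagged outliers
are removed iteratively while the global test stays significant. The
reported global p is the initial test. The distortion test compares the
before/after estimates against removals of equally many random SNPs; it
is reported but never alters estimates automatically. Correlated
pleiotropy acting genome-wide is outside the scope of these diagnostics;
when the global test stays significant with no identifiable outlier the
package surfaces a warning and the corrected-IVW path rather than fitting
a Bayesian shared-factor model.

## MVMR and mediation

Multivariable IVW regresses outcome betas on the J×E matrix of exposure
betas (no intercept, weights 1/σʸ², overdispersion floor on J−E df),
requiring J ≥ E+2 and a full-rank exposure matrix (rank deficiency is an
error naming the collinear exposures). Instruments are the union of each
exposure's clumped genome-wide hits, harmonized to the outcome and
anchored to the first exposure's allele coding.

Mediation decomposes a total effect (univariable MR of exposure on
outcome) using the MVMR direct effect: indirect = total − direct with
se = √(se²_total + se²_direct) (difference method; independence of the
two estimates is assumed — conservative, and their correlation is not
identifiable from summary data), or the product of coefficients
β(x→m)·β(m→y|x) with the first-order delta se. The proportion mediated
is indirect/total with a delta-method CI (a seeded Monte-Carlo
propagation exists behind a flag); it is reported as missing when the
total effect is zero. Negative proportions are reported as-is. A helper
labels a candidate "mediator" when the indirect-path p < 0.05 and
"attenuator/confounder-like" otherwise; the label is advisory, the caller
decides. Mediators are analysed one at a time — no multi-mediator joint
decomposition.

## Drug-target (cis) MR

Gene windows are user-supplied BED-like TSVs with 1-based inclusive
coordinates (±100 kb flank by default); nothing is hard-coded, so any
annotation build can be used. Candidate cis instruments are significant
variants in the window greedily pruned to pairwise r² < 0.30. Because
that threshold admits correlated instruments while plain IVW assumes
independence, a generalized IVW weighting by the full outcome-error
covariance Ωᵢⱼ = σʸᵢσʸⱼrᵢⱼ is provided behind a flag; the run report
records which was used. Estimates are per 1-unit *increase* of the
exposure; interpreting a target-lowering intervention flips the sign. The
FDR family for drug-target results is the set of targets tested in one
run.

## Colocalization

Single-causal-variant enumeration over the variants shared by the two
regions (the intersection is logged). Per-variant Wakefield log
approximate Bayes factors lABF = ½[log(σ²/(σ²+W)) + z²W/(σ²+W)], prior
effect-sd √W = 0.15 for quantitative and 0.2 for binary traits, priors
(p1, p2, p12) = (1e-4, 1e-4, 1e-5) — the conventional defaults of the
field's reference implementation. All sums run in log space
(log-sum-exp). Regions are defined as ±100 kb (closed interval) around
the variant with the smallest p, ties broken by position. No
multiple-causal-variant (SuSiE-style) extension.

## Meta-analysis, FDR, power

Printed OR/CI triplets convert to (log-OR, se) assuming a log-symmetric
CI. Pooling is fixed-effect inverse-variance when I² < 50% (strict
comparison) and DerSimonian–Laird random-effects otherwise. BH-FDR takes
an explicit family size, defaulting to the number of p-values supplied;
a larger declared family uses the family-size multiplier with ranks among
the listed values (a documented approximation for when only the
significant members are listed). Power for a binary outcome uses the
asymptotic variance of the IV log-OR estimate, Var ≈ 1/(n·R²·K(1−K)):
power = Φ(√(n·R²·K(1−K))·|ln OR| − z₁₋α/₂).

## Synthetic-data generator

The generator emulates the statistical structure the estimators assume,
directly on the summary-statistic scale: MAFs uniform on (0.05, 0.5],
true per-SNP exposure effects scaled to a total variance explained
(default h² = 0.08, 100 SNPs — within the 5.8–13.9% / 35–488-instrument
range typical of large lipid GWAS instrument sets), per-SNP standard
errors exactly 1/√(2·MAF(1−MAF)·n), and observed betas = truth + Gaussian
noise. Default sample sizes (1,320,016 exposure; 470,866 outcome;
757,601 mediator) mirror a large lipid-consortium / disease-GWAS /
blood-pressure-GWAS pairing; the default causal effect is θ = 0.1 on the
log-OR scale. Binary outcomes are generated directly on the log-OR scale
with Gaussian sampling noise — adequate for summary-statistic methods and
fast; no individual-level logistic simulation is performed.

Violations on demand: a fraction of SNPs receive direct outcome effects
N(mean, sd²) (uncorrelated pleiotropy; nonzero mean makes it
directional), a fraction load on a shared confounder feeding both traits
(correlated pleiotropy), a mediator chain (a, b, c) produces three-trait
summary sets with true total c + ab and true proportion ab/(c + ab), and
LD blocks with constant within-block r propagate to marginal effects
(marginal = R·joint) and to correlated beta noise. Allele pairs are drawn
from non-palindromic combinations so harmonization is deterministic.
Truth records store every generating quantity including the noise draws:
each observed beta is exactly reconstructable, and a fixed seed
reproduces files bit-for-bit.

What the generator does *not* emulate: realistic genome-wide LD maps,
winner's-curse selection of instruments discovered in the same sample,
sample overlap between exposure and outcome studies, allele-frequency
differences between studies, and non-normal effect-size distributions.
Passing calibration on this generator therefore shows correctness of the
estimators under their stated sampling model, not robustness to those
real-data complications.

## Calibration experiments and chosen conditions

The acceptance experiments (also run by `scripts/acceptance.py`) use:

* IVW coverage / PRESSO size: θ = 0.2, 100 independent SNPs, no
  pleiotropy, 200 replicates. Expected: coverage ≈ 0.95, size ≈ 0.05.
* Planted outlier: 1 of 50 SNPs carries a direct outcome effect of 0.3
  on the log-OR scale (OR ≈ 1.35, a strong pleiotropic locus). The
  magnitude matters only for the "removal moves the estimate toward
  truth" check: detection is essentially certain from ~0.05 upward, but
  the direction of the post-removal shift is dominated by sampling noise
  unless the outlier's bias exceeds roughly 3× the IVW standard error,
  which — since the bias scales with the outlier's own exposure effect —
  requires a planted effect of this size to hold in ≥95% of replicates.
* Mediation recovery: chain (0.2, 0.3, 0.08), true proportion 3/7, 100
  exposure + 100 mediator SNPs, 200 replicates; the delta-method CI for
  the proportion is conservative, so observed coverage sits near 1.
* Colocalization: 100-variant region, exchangeable LD r = 0.3, shared
  causal variant at |z| = 8.

Replicate counts (200 for calibration, 100 for detection) balance
Monte-Carlo error (±1.5–3 percentage points) against desk-scale runtime;
all replicate seeds derive from a single user seed.

## Numerical choices

Normal-theory intervals everywhere (multiplier 1.959964). P-values of
exactly 0 in input files are clamped to the smallest positive double
with a warning (consortium files commonly underflow) rather than
rejected. LD matrices are validated symmetric within 1e-8 then
symmetrized, entries clipped to [−1, 1] after validation. Reading uses
round-trip float parsing so write→read is bit-identical. Clumping and
region ties break by chromosome then position. The cML coordinate ascent
declares non-convergence per K and errors only if every K fails.

## Known limitations

Difference-method mediation ignores the (unidentifiable) covariance of
total and direct estimates. The Egger intercept and PRESSO target
uncorrelated pleiotropy; pervasive correlated pleiotropy requires
genome-wide latent-factor models outside this package's scope. The
weighted-median bootstrap se ignores weight re-estimation uncertainty
beyond beta redraws. Proxy substitution trusts the supplied LD matrix's
sign; no on-the-fly LD computation from genotypes is performed. FDR with
a declared family larger than the listed p-values is an approximation
that assumes unlisted members are non-significant.
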