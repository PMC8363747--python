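# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
written down.

## Two-sample MR estimators

**Wald ratio.**  For one instrument with harmonized exposure association
(β_X, se_X) and outcome association (β_Y, se_Y), the causal estimate is
β̂ = β_Y/β_X.  Two standard errors are offered:

- `first_order` (default): se = se_Y/|β_X|.  This treats the exposure
  association as fixed, which is the usual convention for strong cis-QTL
  instruments (here the instrument F-statistics are in the hundreds), and
  has the algebraic property that β̂/se equals β_Y/se_Y exactly — the MR
  Z-score and p-value are the outcome association's own.
- `second_order`: the delta-method form
  se² = se_Y²/β_X² + β_Y²·se_X²/β_X⁴, adding the exposure-uncertainty term.

Because the first-order ratio preserves the outcome Z exactly, the result
carries the outcome association's *recorded* p-value through when one is
present rather than recomputing it from rounded inputs: a published p
reflects the unrounded Z of the source GWAS, and recomputing
2·Φ(−|β_Y/se_Y|) from, say, a 3-decimal β and SE visibly degrades it (for
the trabecular-vBMD cell, rounded inputs give 1.0×10⁻³ where the source
GWAS reported 9.4×10⁻⁴).  When no p is recorded, the normal two-sided tail
of the computed Z is used.  Second-order results always recompute p from
their own Z.

**IVW.**  Fixed-effect inverse-variance weighting of per-instrument Wald
ratios, with Cochran's Q = Σ(β̂_i − β̂)²/v_i on n−1 df for heterogeneity.
No multiplicative (random-effects) rescaling is implemented: the primary
analyses this package serves are single-instrument, where the distinction
vanishes, and a single instrument reduces IVW to the Wald ratio field by
field.  No pleiotropy-robust estimators (MR-Egger, weighted median,
Steiger filtering) are included — with a single cis instrument they are
not identified, and they are out of scope here.

**Bidirectional MR** is a thin orchestration: IVW on the forward
instrument set and IVW on the reverse set (variants that affect the
outcome-as-exposure directly).  It adds no logic of its own; its value is
the contract that both directions are estimated on harmonized inputs.

**Scales.**  Binary-trait effects live on the log-odds scale everywhere
inside the package; odds ratios are presentation only (`to_or_scale`).
OR→log-odds conversion uses the exact 95% normal quantile 1.959964 rather
than 1.96 so that exp(β ± z·se) reproduces the consumed CI to ~1e-9
relative error; at the 2-decimal precision of published tables the
difference is immaterial.

## Reproduction of the published RSPO3 MR table

`cismr.rspo3` re-derives the published table of causal estimates (2
instruments × 7 outcomes) from the published per-allele associations,
shipped verbatim in `data/table1_rspo3.tsv`.  Points worth recording:

- The published tables do not print the non-effect alleles; the fixture
  assigns non-palindromic placeholder partners (T/C, C/T).  Harmonization
  only ever compares alleles within one SNP, so the choice cannot affect
  any estimate.
- Matching is after rounding to 2 decimals, the published precision.
  Twelve of fourteen cells match.  The two hip-fracture cells do not:
  first-order Wald from the published rounded inputs gives OR 0.85 and
  0.86 where 0.84 and 0.88 were published.  The published values are
  evidently computed from unrounded source estimates; forcing agreement
  would require inventing inputs, so these cells carry a
  `known_discrepancy` flag and are excluded from the pass/fail count.
- MR p-values are the outcome associations' own (see above); the published
  MR table prints p-values that agree with the outcome GWAS p-values in
  most cells, confirming the first-order convention.

## Colocalization

Per-SNP evidence is the Wakefield approximate Bayes factor under a normal
effect prior N(0, W): log ABF = ½[log(1−r) + r z²] with r = W/(W+se²).
Prior effect SDs default to √W = 0.15 (SD units, quantitative traits) and
0.2 (log-odds, case/control), the conventional values for this
approximation; per-SNP hypothesis priors default to p1 = p2 = 1e-4 and
p12 = 1e-5.  All are configurable.

Hypothesis weights are accumulated entirely in log space (`logsumexp`).
The H3 (two distinct causal variants) term is the off-diagonal sum
Σ_{i≠j} ABF1_i·ABF2_j, computed as a log-space subtraction of the diagonal
from the full product; when the subtraction underflows — exactly the
single-SNP case, where no i≠j pair exists — the H3 weight is −∞ and its
posterior is exactly 0.  Posteriors are the softmax of the five weights
and sum to 1 by construction.

A pval/MAF/n input route approximates varbeta ≈ 1/(2n·f(1−f)) for
standardized quantitative traits (with an extra cf(1−cf) factor for
case/control designs); this is an approximation and documented as such —
beta/varbeta inputs are preferred when available.

The method assumes at most one causal variant per trait; loci with
multiple independent signals need decomposition first and are out of
scope, as are reference-panel LD computations.

## Harmonization

Outcome associations are aligned to the exposure's effect allele by label
matching, allowing allele swaps and strand complementation; a flip negates
β and reflects EAF.  Palindromic variants (A/T, C/G) cannot be oriented
from labels: they are oriented by EAF agreement and rejected as ambiguous
when both EAFs fall within a window (default 0.08) of 0.5, or when either
EAF is missing.  The window is configurable; the three SNPs of the shipped
fixture are not palindromic, so the default never triggers there.
Harmonization is idempotent, and flipping is an involution.

## Synthetic cis-locus generator

**What it emulates.**  Individuals receive two haplotypes drawn
independently from an explicit pool of (haplotype, frequency) pairs, so
every allele frequency and every pairwise D′/r² is known in closed form —
LD assertions in tests compare simulated data against `pool_ld` exactly.
The default pool places the causal SNP (frequency 0.50) in r² ≈ 0.74 with
a neighbor, mirroring the linkage between the two real cis-pQTL
instruments, plus an independent third SNP.  Traits follow the structural
equations in the `cismr.simulate` docstring; protein and BMD are
standardized within-cohort before association testing so simulated betas
are on the familiar SD-per-allele scale.  Defaults (β_gp = 0.32 SD/allele,
β_pb = 0.30, fracture intercept −2.2 ≈ 10% prevalence, BMD→fracture slope
−0.62 so one SD of protein maps to fracture OR ≈ 0.83) mirror the
magnitudes of the motivating locus; they are demonstration conditions, not
fitted quantities.

**Reverse-direction instruments.**  `direct_bmd_effects` gives chosen SNPs
a direct genotype→BMD effect.  Without such a SNP the generative model has
no valid reverse instrument (every genotype→BMD path runs through the
protein, so instrumenting BMD with the protein SNP would "detect" reverse
causation by construction).  A direct-BMD SNP in linkage equilibrium with
the protein SNP is the locus-scale analogue of the genome-wide BMD
instruments used in real bidirectional MR.

**Association models.**  Continuous traits: per-SNP simple linear
regression, p from the t distribution on n−2 df, SE floored at the
smallest positive double for pathological zero-residual fits.  Fracture:
per-SNP logistic regression by IRLS (tolerance 1e-8 on the coefficient
update, max 50 iterations), SEs from the observed information; separation
(diverging coefficient with vanishing weights) and non-convergence yield a
flagged row with missing SE rather than a penalized fit.  Monomorphic SNPs
are skipped with a warning.  Tests cross-check the IRLS fits against
statsmodels GLM to 1e-6.

**What it does not emulate.**  No covariates (age, sex, ancestry
principal components), no relatedness or mixed-model association, no
genotyping error or imputation uncertainty, no sample overlap between
"exposure" and "outcome" studies, no winner's-curse selection of
instruments.  Passing recovery tests therefore show the estimators are
correct and calibrated under the model's own assumptions — not that those
assumptions hold in any particular real cohort.

**Estimand.**  Because traits are standardized, the recovery target is
the standardized mediation effect β_pb·sd(protein)/sd(BMD), computed in
closed form from the pool frequencies and noise SDs
(`standardized_mediation_effect`); the reported bias/RMSE/coverage are
against this quantity.

**Problem sizes.**  The validation suite runs the recovery experiment at
500 replicates of n = 20,000 (CI coverage within [0.93, 0.97], |bias| <
0.01) and the shared-signal colocalization scenario at 200 replicates of a
50-SNP locus with n = 8,000 chosen so the per-trait causal-SNP |z| exceeds
8 (PP.H4 > 0.9 in ≥ 90% of replicates).  Unit-level stochastic checks use
smaller cohorts with the same generative structure.  All simulation seeds
are fixed; every generator output is bit-reproducible from its config.

## Numerical and degenerate-input decisions

- p-values below double-precision range (published GWAS p-values reach
  10⁻³³⁶) are clamped to the smallest positive double on input rather than
  underflowing to an invalid 0.
- Zero-width confidence intervals, non-positive SEs, EAFs outside [0,1],
  identical alleles, non-polymorphic loci, frequency vectors that do not
  sum to 1, and empty instrument lists all raise typed validation errors
  naming the offending row where applicable.
- LD D′ at d = 0 is defined as 0 (the normalizing maximum is otherwise
  undefined at independence).
- `ivw` refuses to pool instruments whose outcomes mix linear and
  log-odds scales.
- Effect-size comparison assumes independent estimates (cov12 = 0) by
  default; a covariance argument accommodates overlapping samples, but no
  overlap correction is estimated by the package itself.

## Known limitations

- Single-causal-variant colocalization only; no SuSiE-style multi-signal
  decomposition.
- No proxy-SNP lookup, liftover, or VCF/GWAS-VCF ingestion; input is the
  whitespace/TAB summary-statistics dialect.
- The effect-comparison Z-test and the MR estimators take summary
  statistics at face value: sample overlap, winner's curse and weak
  instruments are the analyst's responsibility to assess.
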