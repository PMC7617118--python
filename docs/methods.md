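# Methods

## The case-only mitonuclear scan

Mitochondrial DNA is haploid and maternally inherited, so each mtSNP is a
binary allele indicator `M ∈ {0,1}`; nuclear SNPs are diploid dosages
`G ∈ {0,1,2}` counting the cohort-minor allele. The scan fits, per
(mtSNP, nSNP) combination and per cohort,

```
logit P(M=1) = a + β·G + γᵀPC,
```

by maximum likelihood and reports the Wald test of β with `exp(β)` as the
mitonuclear odds ratio. The FDR family is **all** combinations examined
in a run (every scanned mtSNP times every nSNP), adjusted by
Benjamini–Hochberg; per-mtSNP q-values would understate multiplicity.

Rationale. Within a well-mixed population, independent transmission of
the two genomes makes `M ⊥ G`; enrichment of a combination among affected
individuals implies an interaction effect on risk. Under a rare disease
and population-level independence, the within-case OR equals the
interaction OR of the logistic risk model — the identity the
`interact.risk_interaction_test`/`case_only_scan` concordance checks
numerically (median ratio ≈ 1.01 at prevalence 0.01 in the acceptance
suite).

Confounding. Because mtDNA lineages track ancestry, stratification
produces spurious mitonuclear association. All models accept leading
per-sample covariates (by convention PC scores from the nuclear matrix,
`simcohort.compute_pcs`: columns centred at `2p̂`, scaled by
`√(2p̂(1−p̂))`, mean-imputed, left singular vectors × singular values).
Diagnostics are the genomic inflation factor λ (median implied 1-df
chi-square over 0.4549…) and Q–Q coordinates with expected quantiles
`−log10((i−0.5)/m)`.

## Combined-cohort models

For combinations that pass the per-cohort scan, two further logistic
models on the pooled cohorts:

* **Modulation**: `logit P(M=1) = a + β₁G + β₂D + β₃(D×G) + γᵀPC`, with
  disease status `D`; β₃ measures how the mitonuclear association
  differs between strata. The disease main effect is kept so the
  interaction term is interpretable.
* **Risk interaction**: `logit P(D=1) = a + β₁M + β₂G + β₃(M×G) + γᵀPC`;
  `exp(β₃)` is the combination's effect on risk beyond the main effects.
  Case-control ascertainment biases only the intercept of this model, so
  β₃ is estimated consistently at any sampling ratio.

Marginal single-variant disease associations (haploid indicator for mt,
dosage for nuclear) complete the five fits assembled per combination by
`interact.combination_report`.

## Logistic fitting

`scanner.fit_logistic` is a Newton/IRLS solver: tolerance 1e-8 on the
log-likelihood, at most 50 iterations, step-halving when a Newton step
overshoots, Wald standard errors from the inverse observed information.
A fit is flagged `separation` when a fitted probability sits within 1e-8
of 0/1 together with a coefficient exceeding 15 in absolute value, and
such results carry no numeric estimate. Tests whose genotype classes are
present but thinner than `min_cell_count` (default 5) are skipped rather
than fitted; an entirely absent class only reduces the coding and is
allowed. The solver is cross-checked against statsmodels `Logit` in the
test suite; a dedicated implementation keeps the multi-thousand-test scan
fast.

## Analytic power and mtSNP eligibility

The eligibility question — how common must an mtSNP be for the scan to
see an OR of 1.5? — is answered on a person-level 2×2 table crossing the
mt allele (frequency `maf_mt`) with nuclear minor-allele **carrier**
status (frequency `1−(1−maf_n)²`). Given the two margins and the odds
ratio θ, the joint cell `p11` is the admissible root of
`(θ−1)x² − [(θ−1)(p_r+p_c)+1]x + θ p_r p_c = 0`; the Wald power uses the
normal approximation for the log-OR with variance `Σ 1/(n·p_ij)` under
the alternative (so power equals α exactly at θ=1, with no continuity
correction). `minimum_mt_maf` inverts by bisection on (0, 0.5] to 1e-4;
power is unimodal in `maf_mt` (increasing until close to 0.5), which the
bisection's smallest-crossing property tolerates. When even MAF 0.5
falls short, the result is reported unachievable together with the power
attained there — which is what happens at α = 5×10⁻⁸ with n = 2000 and
OR = 1.5 (best power ≈ 0.03), whereas at α = 0.05 the threshold lands
near MAF 0.16–0.2, the range in which mtSNP eligibility cutoffs of
"MAF > 0.2" are typically quoted. Carrier (dominant) coding makes the
construction closed-form; the scan itself defaults to additive dosage,
and the Monte-Carlo oracle (`simcohort.power_experiment`) uses the same
dominant coding so the analytic and empirical routes are comparable
(agreement within 3 binomial SE at every grid point tested).

## mtSNP selection

`mtselect.prune_mtsnps` drops mtSNPs with haploid MAF below the
eligibility minimum (default 0.2), connects pairs with squared Pearson
correlation strictly above the threshold (default 0.9) over jointly
non-missing calls, and keeps one representative per connected component:
the highest-MAF member, ties broken by smallest position. The
representative rule is a package choice — any member of a near-perfectly
correlated cluster carries the same information. R² that is undefined
(monomorphic joint support) never links a pair.

## The synthetic cohort generator

`simcohort.simulate_cohort` produces the statistical structure the scan
must tolerate, not a coalescent-realistic genome:

* **Ancestry**: each individual draws a subpopulation from
  `subpop_weights`; per-subpopulation allele frequencies follow the
  Balding–Nichols Beta distribution with mean equal to the ancestral
  frequency and variance `Fst·p(1−p)`. Mitochondrial frequencies may be
  fixed per subpopulation (`mt_freqs_by_subpop`) to create the
  mt–ancestry confounding that motivates PC adjustment.
* **LD**: haplotype alleles inside fixed-size blocks (default 10 SNPs)
  are thresholded latent Gaussians with first-order autoregressive
  correlation (default 0.7 on the latent scale); blocks are independent,
  so the genome-wide null stays exact. This yields correlated
  neighbourhoods without recombination maps.
* **Disease**: a logistic model on the log-odds scale with optional
  nuclear, mitochondrial and interaction effects. The default intercept
  sets prevalence 0.01 so the case-only identity holds in tests. Cases
  and controls are collected by rejection sampling to exact counts
  (default 2000 + 2000, the cohort scale the power analysis assumes),
  mimicking separately ascertained cohorts; a draw budget of 10⁷ guards
  against infeasible models.
* **Coupling**: for power experiments a designated (mt, nuclear) pair is
  drawn jointly from the margins-plus-OR 2×2 table (carrier status split
  into het/hom by HWE conditionals). Coupling is defined for
  single-subpopulation configurations only.

What the generator does **not** emulate: realistic recombination and
allele-frequency spectra, genotyping error, relatedness, X chromosome,
heteroplasmy, and mtDNA phylogenetic structure. Passing tests therefore
demonstrate statistical correctness of the methods under the stated
generative assumptions, not robustness to every artefact of real array
data.

## Numerical and design choices

* Missing data: per-test complete-case analysis (samples missing the
  variant or any covariate are dropped; `n_used` is reported).
* Minor alleles are defined per cohort at read time; columns whose ALT
  allele is major are flipped and REF/ALT swapped so dosage always counts
  the minor allele. Heterozygous/heteroplasmic MT calls become missing —
  the haploid representation cannot express them.
* q-values use statsmodels' BH implementation (verified against a
  brute-force step-up oracle on 1000 random vectors).
* λ uses the full-precision 1-df chi-square median, not 0.456.
* Covariates default to the first 10 available; every acceptance-grade
  simulation states its `k` explicitly.
* p-values are floored at 1e-300 to keep downstream `log10` finite.

## Problem sizes used in the deep checks

The statistical test-suite checks run, per replicate, cohorts of 2000
individuals: the global-null calibration uses 20 replicates of 4
mtSNPs × 1250 nSNPs (5000 combinations each; KS uniformity assessed on
one SNP per LD block, which are mutually independent); stratification
control uses 6 replicates of 2000 SNPs with λ pooled across replicates
(per-replicate λ on 2000 tests has sampling noise of ±0.07, too coarse
for a ±0.05 band); parameter recovery and the modulation size use 500
replicates at n = 4000; the case-only identity 500 replicates at
prevalence 0.01; power agreement 250 Monte-Carlo replicates per grid
point, compared at 3 binomial standard errors computed from the analytic
power. `scripts/acceptance.py` repeats the same computations at slightly
smaller replicate counts (10/5/300) and records every measured value.
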