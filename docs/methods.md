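# Methods

This note documents the statistical model, the numerical choices, and the
design decisions behind `mvgwas`, together with what the synthetic-data
generator does and does not emulate.

## Generative model and Bayes factor

The unit of analysis is one SNP's vector of signed Z-scores
`z = (z_1, …, z_d)` across `d` phenotypes measured on overlapping samples.
Under the global null, `z ~ N(0, R)` with `R` the *null correlation*: with
fully overlapping samples the phenotype correlation leaks into the noise of
the score statistics, so `R` is close to the phenotypic correlation matrix;
with disjoint samples it would be the identity.

An alternative model γ partitions phenotypes into sets (U, D, I):

* **U** (code 0) — unassociated: no connection with the genotype;
* **D** (code 1) — directly associated: the genotype shifts the phenotype's
  score;
* **I** (code 2) — indirectly associated: connected to the genotype only
  through the D phenotypes, i.e. the conditional law of `z_I` given
  `(z_U, z_D)` is the same under γ and under the null.

Conditional on `z_U`, each D phenotype's *standardized* direct effect has
an independent `N(0, σ²)` prior, and a standardized effect `b_j` shifts
that phenotype's Z-score by `√n_j · b_j` (each phenotype keeps its own
sample size — meta-analytic releases routinely report different `n` per
phenotype). Because the I factor cancels from the likelihood ratio, the
Bayes factor reduces to a ratio of two Gaussian densities of the
conditional `z_D | z_U`:

    BF_γ = N(z_D; m, Σ + σ² diag(n_D)) / N(z_D; m, Σ)
    m = R_DU R_UU⁻¹ z_U,   Σ = R_DD − R_DU R_UU⁻¹ R_UD.

Consequences worth stating explicitly:

* the all-U model has `BF = 1` identically;
* a model containing I phenotypes but **no** D phenotype gives the genotype
  no path into the data and is observationally null-equivalent; such models
  are kept in the `3^d` enumeration (they are distinct causal statements)
  but carry `BF = 1` exactly;
* `BF_γ` does not depend on the I coordinates of `z` at all.

The closed form is validated in the test suite against an independent
oracle that integrates the *full joint* density over the direct-effect
prior numerically (mode-centered Gauss–Hermite quadrature; plain quadrature
on the prior scale fails when `√n·σ` is large because the integrand is then
far narrower than the prior). Agreement is required to 1e-4 in log10 and is
observed at ~1e-11.

All Bayes factor arithmetic is done in natural-log space; tables report
log10. Averages and posteriors use log-sum-exp throughout.

## Null correlation estimation

`R̂` is the sample correlation of the Z-score vectors over *empirically
null* SNPs, defined as those with `max_p |z_p| < zmax`, with `zmax = 2` by
default. Two caveats, both deliberate:

* The truncation at `zmax` slightly attenuates off-diagonals (tails carry
  the correlation signal); at `zmax = 2` and true correlation 0.3 the bias
  is around −0.05. This attenuation is tolerated because the alternative —
  including signal SNPs — inflates `R̂` with genetic rather than noise
  correlation and is far more damaging to the Bayes factors.
* A non-positive-definite estimate (possible after missing-data patterns or
  duplicated phenotypes) is repaired by flooring eigenvalues at 1e-8 and
  re-standardizing to unit diagonal; the repair is recorded on the result
  object.

An estimation error naming `zmax` is raised when fewer than 50 qualifying
SNPs exist.

## Model space and weights

The `3^d` assignments are enumerated in base-3 ascending order (phenotype 1
the most significant digit), so the null model is always index 0 and weight
vectors are reproducible across runs. The exhaustive enumeration is the
method; `d` is capped at 10 by default (the capacity error reports `3^d`).

Weights for the averaged Bayes factor are learned jointly over
(model, prior-scale) pairs by EM on the training SNPs — in the intended
workflow, the previously reported univariate associations. Because every
BF is a likelihood ratio against the same null density, maximizing
`Σ_i log Σ_{γ,σ} w_{γ,σ} BF_i(γ,σ)` over the simplex is an ordinary
mixture-weight problem: responsibilities `∝ w·BF`, weight update = mean
responsibility. The objective is non-decreasing by the EM guarantee and is
asserted per-iteration in tests. Defaults: uniform initialization,
`tol = 1e-6` (largest relative weight change; the denominator is floored at
1e-6 so components decaying geometrically toward zero cannot stall the
criterion), `max_iter = 10000`. The null model is excluded from training —
training SNPs are by construction associated — but a configurable null
prior mass is available when computing per-SNP posteriors.

Reported model weights are σ-summed; the prior-scale grid defaults to
σ ∈ {0.05, 0.1, 0.2, 0.4} on the standardized-effect scale and is
user-configurable. With `n = 50 000`, these correspond to Z-shift scales
`√n·σ ≈ 11–89`, i.e. the grid spans modest to very strong effects; the EM
weights, not the grid, decide what matters in a given dataset.

Per-phenotype category probabilities are sums of model posteriors over the
models placing the phenotype in the category; "confidently associated"
means `P(D) + P(I) > 0.95` *strictly*, "confidently unassociated"
`P(D) + P(I) < 0.05` strictly.

## Significance, pruning, classification

* The multivariate significance threshold is the smallest `log10 BF_av`
  among the previous univariate hits; comparison is strict
  (`BF_av > threshold`).
* Distance pruning keeps the unique fixed point of "no survivor has a
  strictly higher-scoring survivor within the window on the same
  chromosome": scan in descending score (ties to the smaller position),
  keep a SNP iff no kept SNP lies within the window. A simultaneous-pass
  reading of the rule is not a consistent fixed point (a SNP could be
  removed by a SNP that is itself removed); the sequential fixed point is
  idempotent and matches a brute-force simulation exactly in tests.
* New multivariate hits must additionally lie strictly more than the window
  (default 500 kb) from every previous hit; exclusion happens before
  pruning, and both intermediate counts are recorded.
* Low-MAF (`MAF < 0.01`) and weak-univariate (`min p > 1e-4`) flags are
  diagnostics only and never filter: very-low-frequency SNPs can show
  strong multivariate signals with little univariate support, and such
  hits deserve caution rather than silent removal. The two cutoffs are
  package defaults for an effect the source procedures describe only
  qualitatively.
* The relaxed-univariate comparison builds the "marginally significant"
  list (`p < 1e-6` but not genome-wide significant), prunes it by minimum
  p, removes entries within the window of a new multivariate hit, merges
  with the new hits and sorts by minimum univariate p, reporting cumulative
  per-category counts.
* Threshold-crossing comparisons on p-values use `≤` ("attains the
  threshold"); BF significance is strict, matching "exceeds".

## Replication across releases

Later releases include the earlier samples, so the cross-release check is
an *enrichment* test, not independent replication — the report header says
so. A hit "improves" when its minimum univariate p at exactly the same
`snp_id` (not positional matching) is strictly smaller in the later
release; "crosses" when the later minimum p attains the later release's
threshold. Overlap with later univariate hits uses a closed ±50 kb window.
Hits absent from the later panel are reported unmatched and excluded from
denominators; improved + not-improved + unmatched always equals the hit
count.

## Synthetic data

`simulate_panel` draws, per SNP: a (model, σ) component from a configured
mixture; standardized direct effects `b_D ~ N(0, σ²)` (optionally one
shared draw for all D phenotypes, giving shared-direction effects); the
marginal mean `μ` with `μ_D = √n·b`, `μ_U = 0` and
`μ_I = R_{I,UD} R_{UD,UD}⁻¹ μ_{UD}` (the DAG-consistent induced mean); then
`z ~ N(μ, R)`. Output is the canonical per-phenotype TSV dialect
(`snp, chr, bp, ref, alt, af, beta, se, pvalue, n` with `beta = z/√n`,
`se = 1/√n`), byte-reproducible from the seed. Positions are laid out at
fixed spacing on synthetic chromosomes purely so pruning logic is
exercised.

`simulate_two_releases` shares one set of true effects and builds the late
noise as `√(n_e/n_l)·ε_early + √(1 − n_e/n_l)·ε_extra` with both pieces
`N(0, R)`; the per-phenotype early–late null correlation `√(n_e/n_l)` is
exact. When the growth ratio differs across phenotypes the late release's
*cross-phenotype* noise correlation deviates slightly from `R`; all
two-release configurations used in the tests grow proportionally.

What the generator does **not** emulate, and hence what passing tests do
not establish about real data: linkage disequilibrium between SNPs (the
method treats SNPs independently and prunes by physical distance only),
MAF-dependent sampling noise (summary statistics are standardized; an
optional contamination mode injects inflated Z-scores at very low MAF
solely to exercise the diagnostic flags), population stratification,
covariate adjustment, and binary-trait likelihood approximations.

## Problem sizes and numerical settings in the validation suite

The validation runs use sizes chosen to give stable Monte-Carlo estimates
on a single CPU: 50 random instances for the quadrature comparison; 1e5
null SNPs at `d = 4` for calibration, with `n·σ² = 0.25` because the
variance of a null Bayes factor is finite only when `n·σ²` stays below the
smallest eigenvalue of the conditional null covariance (heavier priors
make the MC mean of BF unstable even though its expectation is exactly 1);
2 000 training SNPs for EM recovery of (0.7, 0.2, 0.1); 20 replicates of
3 000 SNPs at `d = 4`, `n = 50 000`, 5% non-null, `σ = 0.015`
(`√n·σ ≈ 3.4`, the partial-power regime where method ranking is
informative) for the power comparison; and 20 000 SNPs for the two-release
checks. The end-to-end scan uses `σ = 0.02` (`√n·σ ≈ 4.5`): with much
stronger effects essentially every true locus is already univariate
significant and there is nothing left for the joint analysis to add, which
is itself worth knowing about the method's niche.

## Known limitations

* Direct vs. indirect classification is fragile in practice: distinct
  (D, I) assignments with similar induced means are hard to separate, and
  with many correlated phenotypes most associated SNPs end up confidently
  associated with many phenotypes while confident *unassociation* is rare
  (weak association and no association cannot be distinguished).
* The null-correlation truncation bias above; a larger `zmax` trades it
  against signal contamination.
* The large-`n` normal approximation is assumed throughout; no
  finite-sample t corrections.
* Strand-ambiguous (A/T, C/G) variants are flagged, not resolved; allele
  orientation requires the effect-allele frequency column.
* No LD-aware pruning (`r²`); physical distance only.
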