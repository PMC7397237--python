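# Methods

## Model and assumptions

All evaluations are single-trait animal models y = Xb + Wu + e with one or
more independent random genetic effects and residual e ~ N(0, Iσ²ₑ/w) for
optional per-record weights w. Variance components are inputs, never
estimated. Fixed effects are cross-classified factors with no explicit
constraints; the worked models (sex + animal) are full rank, and a
rank-deficient fixed part makes the direct solver fail with a message
naming duplicated equations while conjugate gradients returns a
least-squares solution with a logged warning.

The genetic covariance structure is, per effect, one of:

* **pedigree** — A from the tabular recursion (oracle only); sparse A⁻¹ by
  Henderson's rules. Mendelian-sampling variances are 0.5 − 0.25(F_s+F_d),
  0.75 − 0.25F_known, or 1 for two/one/zero known parents. With
  `inbreeding: true` (default) the F are Meuwissen–Luo coefficients and
  A⁻¹ is the exact inverse of A; with `false` all F are zero — the
  classical approximation that is harmless in plain BLUP but degrades
  single-step, and both paths exist precisely so that contrast is
  reproducible.
* **genomic** — G = ZDZ′k, Z = M − 2p′, k = 1/(2Σpq), D per-SNP weights.
  Missing genotypes are imputed to the column mean (zero after centering),
  which keeps every column of Z sum-zero under observed frequencies.
  Allele frequencies default to the observed data; user-supplied base
  frequencies are accepted (and are what make G full-rank in the exact
  GBLUP ≡ SNP-BLUP identities, since observed-frequency centering leaves
  1 in the null space of G).
* **single-step** — H⁻¹ = A⁻¹ + [0 0; 0 τG⁻¹ − ωA22⁻¹], never materialized
  densely: it is stored as sparse A⁻¹ plus a dense genotyped-block
  correction and enters the solver through matrix-vector products. A22 is
  computed by Colleau's indirect A·v products (one O(n) sweep pair per
  genotyped animal), A22⁻¹ as A²² − A²¹(A¹¹)⁻¹A¹² via sparse LU solves.
* **user file** — a symmetric covariance inverse read from triplet text
  (e.g. a saved H⁻¹); several such effects may be fitted at once, one per
  SNP set, and the per-animal total genetic effect is the sum of the
  effect solutions.

## G preparation

Default pipeline order: QC → center → build → tune(type 2) → blend
(α = 0.95 against A22). Tuning before blending follows the rationale that
base-population compatibility should be estimated from the marker-only
matrix; the order is configurable territory in principle but fixed here.
Chen's type-2 tuning G* = φG + δ matches the mean diagonal and mean
off-diagonal of A22 exactly; type-4 applies the single mean shift ρ with
G* = (1 − ρ/2)G + 11′ρ. The multiplicative part (φ, or 1 − ρ/2, or 1) is
recorded as the `b_factor` used in the SNP-effect PEV.

QC drops monomorphic SNPs always, then SNPs with call rate < 0.90 or
MAF < 0.05 (minor allele, regardless of which allele is counted), then
animals with call rate < 0.90 over the retained SNPs. These thresholds
are package defaults chosen as conventional chip-data practice, not
values taken from a reference implementation. `no_quality_control`
bypasses everything. SNP weights supplied for the full panel are
restricted to the QC-surviving columns and rescaled to sum to the number
of SNPs actually used.

## Unknown-parent groups

Negative parent codes become group slots. Quaas rules give A⁻¹ the extra
group columns (cross terms only, no own diagonal unity; Mendelian
variances keep treating a group parent as unknown). `exact_upg` extends
the groups into the genomic block through the ancestral-fraction matrix
Q2 (q(i) = ½q(sire) + ½q(dam), a group parent contributing its unit
vector): the correction block gains −SQ2 and Q2′SQ2 with
S = τ_q2·G⁻¹ − ω_q2·A22⁻¹. (τ_q2, ω_q2) = (1, 1) is the full
Quaas–Pollak transform — verified in the tests against a dense model that
fits the groups explicitly as covariates — and (0, 1) keeps groups in the
pedigree terms only. Default is no genomic UPG, reflecting the mixed
evidence on whether genomic relationships need group corrections at all.

## Solvers

Direct solution is a dense Cholesky factorization, guarded at 20,000
equations; it is the test oracle and the only route to the inverse-LHS
block C^{u2u2} required for SNP p-values. The production solver is
Jacobi-preconditioned conjugate gradients (scipy's CG on a LinearOperator
composing the sparse and dense parts), convergence at relative residual
1e-12, max 5000 iterations; non-convergence is flagged on the Solutions
object, not raised.

## SNP effects and GWAS

Backsolving uses â = kDZ′G⁻¹û with the inverse of the *same* final
(tuned, blended, weighted) G used in the evaluation. Per-SNP variance
formulas: default 2pq·â², quadratic â², and nonlinearA
CT^(min(|â|/σ(â), limit) − 2) with CT = 1.125 and limit 5 by default
(cap CT^(limit−2); the cap applies per round when iterating). Weighted
iteration follows the loop D = I → G → solve → backsolve → reweight →
normalize (Σd = m) → repeat; external weights replace the reweighting
step after the same Σd = m rescaling. The PEV of â_i is
(kαb)²·z_i′G⁻¹(Gσ²ᵤ − C^{u2u2})G⁻¹z_i, where C^{u2u2} is the genotyped
block of the inverse LHS times σ²ₑ (so Gσ²ᵤ − C^{u2u2} is the variance of
û) and b is the recorded tuning factor — defined in the source derivation
only for the mean-shift tuning as 1 − ρ/2; using φ under type-2 tuning is
this package's extension of the same role, surfaced in the output
metadata. p = 2(1 − Φ(|â|/sd)); non-positive computed variances are
floored (p = 1). p-values are refused in combination with weighted
iteration, since the weights are functions of the very effects being
tested. Window variance shares are sliding sums (within chromosome,
truncated at its end) of 100·2pqâ²/Σ2pqâ².

## APY

The generalized inverse G_APY⁻¹ uses a random core (reproducible by
seed; the strategy field is extensible but only "random" is implemented,
as no particular selection rule is required). The core block of the
final — tuned and blended — G is inverted densely (guard 20,000); noncore
conditional variances m_ii = g_ii − g_ic G_cc⁻¹ g_ci must be positive,
which blending guarantees in practice. Storage is n_c² + 2n_c·n_n + n_n
nonzeros; noncore–noncore off-diagonals are exactly zero. Accuracy
relative to the full inverse depends on the core size reaching the
number of independent chromosome segments; the validation test therefore
simulates a deliberately low-dimensional population (300 ancestral
haplotypes, one short chromosome) where a 300-animal core suffices for
GEBV correlation ≥ 0.98.

## Simulator

The generator emulates a livestock nucleus population: discrete
generations, balanced sexes, n_sires/n_dams drawn per generation,
Mendelian gene dropping with Haldane recombination (Poisson crossovers,
1 cM ≈ 1 Mb), founder haplotypes composed as mosaics of a limited
ancestral pool (default 100 haplotypes, 10 crossovers/Morgan of
historical recombination) so that markers carry realistic linkage
disequilibrium with QTL. QTL are excluded from the SNP panel by default
(chips tag causatives through LD); `include_qtl_in_panel` supports
perfect-prediction experiments and `equal_qtl_variance` planted-QTL
designs. True breeding values are scaled so Var(TBV) equals σ²ᵤ exactly
across all animals; phenotype = sex effect + TBV + N(0, σ²ₑ). Defaults:
3000 animals (500 founders + 5×500), 2000 SNPs on 5 chromosomes of
100 cM, 50 QTL, σ²ᵤ/σ²ₑ = 0.4/0.6, sex effects 2.0/1.0, genotyping of
generations 4–5. A companion-shape preset reproduces the observable
shape of the published example dataset (10,000 animals; 1020 genotyped
parents of generations 1–4 plus 1004 generation-5 animals).

What the simulator does **not** emulate: selection (matings are random),
overlapping generations, mutation, genotyping error, non-additive
effects, and real LD decay shaped by long-term population history.
Passing validation tests therefore demonstrate internal consistency and
the expected qualitative behaviour (e.g. single-step ≥ BLUP accuracy for
unphenotyped genotyped juveniles), not field accuracies.

## Numerical choices and degenerate inputs

* Dense-build guards: 20,000 (tabular A, direct solver, APY core).
* Symmetrization after every dense assembly (0.5(M + M′)) to shed
  accumulated asymmetry.
* Tie-breaks: renumbering is a topological sort with ties by first
  appearance in the file, making the cross-reference deterministic.
* Type-2 tuning fails loudly when mean diag G equals mean offdiag G;
  blending is the prescribed remedy for singular G (and for singular
  APY core blocks).
* Empty genotyped sets are legal in the H⁻¹ assembly (reduces to A⁻¹);
  an all-monomorphic panel (k undefined) and an all-removed QC result
  are errors.
* All text output is ASCII with "." decimals, 8-decimal solutions.

## Problem sizes used in validation

Oracle equivalences run at 20–400 animals; the stochastic recovery study
uses the default 3000-animal preset over ten seeds with generation-5
phenotypes masked; the null-GWAS calibration uses ten replicates of 400
animals × 1000 SNPs; the APY study uses 1500 genotyped animals. These
sizes were chosen as the smallest at which the respective statistical
contrasts are stable.
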