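# Methods

## Scope

`ssgblup` implements a complete single-step genomic evaluation and genome
scan for a multibreed beef-cattle setting: pedigree and genomic
relationship matrices combined into the joint matrix H, variance components
by average-information REML (AI-REML), genomic breeding values (GEBVs) from
Henderson's mixed-model equations, an iterative weighted single-step GWAS
(WssGBLUP) whose association statistic is the percentage of direct additive
genetic variance explained by 1-Mb windows, a conditional (all other traits
as covariates) scan to separate direct from mediated genetic effects, and a
cross-trait overlap rule that classifies windows into pleiotropic and
suggestive pleiotropic regions with candidate-gene flagging.  A synthetic
population generator provides ground truth for all of it.

## Models

### Animal model

Single trait:

    y = Xb + Wu + e,   u ~ N(0, H sigma_u^2),   e ~ N(0, I sigma_e^2)

`X` holds year-of-birth classes (one dummy per level, no intercept) and a
centered age-at-slaughter covariate; age is omitted for TEND and FLAV,
where it is not a significant effect.  Each animal contributes at most one
record per trait.  Two traits:

    u ~ MVN(0, T (x) H),    e ~ MVN(0, R (x) I)

with full 2x2 genetic (T) and residual (R) covariance matrices; `(x)` is
the Kronecker product.  Derived quantities: h^2 = sigma_u^2/(sigma_u^2 +
sigma_e^2), r_g = T12/sqrt(T11 T22), r_p = (T12+R12)/sqrt((T11+R11)(T22+R22)).

### Relationship matrices

- `A` by the tabular method; inbreeding F = diag(A) - 1.
- `A^-1` by Henderson's rules with Meuwissen-Luo inbreeding: the
  within-family variance d_i is 0.5 - 0.25(F_s + F_d) with both parents
  known, 0.75 - 0.25 F_p with one, 1 otherwise, and alpha_i = 1/d_i is
  scattered over the (animal, parent) block.
- `G = Zc D Zc' / (2 sum p_i(1-p_i))` with `Zc` the genotype matrix centered
  at observed frequencies (missing calls imputed to 2p, hence zero after
  centering) and `D` the per-marker weights (identity when unweighted).
  An exactly centered G is always singular (its rows sum to zero), so the
  inverse is taken of the blend `G* = 0.95 G + 0.05 A22`.
- `H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1]`, added into the genotyped block
  identified by an index vector; animals are never reordered.

### AI-REML

Because every animal has at most one record per trait, the phenotyped
sub-block K of H can be eigendecomposed once (K = U S U').  In the rotated
basis all covariance derivatives are simultaneously diagonal (single trait)
or 2x2 block diagonal (two traits sharing a record set), so the restricted
likelihood, its gradient and the average-information (AI) matrix are exact
at O(n p^2) per iteration instead of O(n^3).  Updates are Newton steps on
the AI matrix with:

- single trait: an EM-REML fallback step whenever the AI update would leave
  the parameter space or reduce the likelihood; variance floor at
  1e-8 x phenotypic variance so h^2 stays defined;
- two traits: step-halving of the AI step (retrying along the
  diagonally-preconditioned gradient) with a positive-semidefiniteness
  check on T and R; a literal EM step for covariance matrices would need
  mixed-model-equation traces the spectral path does not form, so
  safeguarded step-halving plays that role here.  An ill-conditioned AI
  matrix (near-degenerate data, e.g. duplicated traits) is handled by
  capping the step at twice the parameter scale.
- two traits on *different* record sets: a dense AI-REML path with the
  residual covariance contributing only for animals recorded for both
  traits.  This path is O(n^3) per iteration and intended for moderate n.

Convergence: maximum relative parameter change below 1e-9 (single trait) /
1e-8 (bivariate), at most 200 rounds; non-convergence is flagged and the
last values returned.  Starting values are half the phenotypic
(co)variance.  Standard errors come from the inverse AI matrix at
convergence with the delta method for h^2 and r_g; they are approximate
(curvature-based) and labelled as such.

Both likelihood evaluators were verified against central finite differences
of the restricted likelihood, and the balanced paternal half-sib case
against the closed-form ANOVA estimators (REML and ANOVA coincide for
balanced one-way data; the animal model on half-sib progeny is a linear
reparameterization of that model).

### Weighted single-step GWAS

Marker effects are backsolved from the GEBVs of the genotyped animals,

    a_hat = lambda D Zc' G*^-1 u_hat,    lambda = 1/(2 sum p_i(1-p_i)),

with the proportionality constant chosen as lambda so that in the unblended
full-rank case `Zc a_hat = u_hat` exactly (verified against an independent
dense ridge/SNP-BLUP solve).  The nonlinearA weights are

    d_i = 1.05^(|a_i|/sd(a) - 2),

capped at 10 before normalization, then normalized so sum d_i equals the
marker count (keeping the implied additive variance constant).  Three
weighting iterations are the reporting default; variance components stay
fixed at their AI-REML estimates throughout.  The window statistic is

    Var(sum_{j in window} Zc_j a_hat_j) / sigma_u^2 x 100

computed across genotyped individuals with the population variance
(divide by n) — the natural scale for a variance share; using the sample
variance would change results by n/(n-1).  Two window schemes are
available: a fixed 1-Mb grid per chromosome (default) and marker-anchored
sliding 1-Mb windows (the per-trait window counts and trait-specific window
boundaries in published analyses are consistent with sliding windows).

### Pleiotropy classification

Per trait, windows explaining more than 1% of sigma_u^2 are associated and
windows in [0.9%, 1%] form the suggestive band.  Overlapping (closed
intervals, transitive clustering per chromosome) associated windows of two
or more traits make a pleiotropic region; an associated window overlapping
a suggestive-band window of a *different* trait makes a suggestive region.
Region bounds are the intersection of the member windows (associated
members only for pleiotropic calls); the union is retained alongside, and
an empty transitive intersection falls back to the union with a warning.
Within a region, markers rank by the largest |a_hat|/sd(a_hat) across the
member traits (per-trait standardization, since effects live on different
trait scales), ties at the cutoff break by bp position, and genes whose
span contains one of the top 20 markers are flagged.

## Synthetic data generator

What it emulates: a closed multibreed herd (breed fractions 0-1 with both
purebred endpoints among founders; a non-founder's fraction is exactly the
parental mean), year-of-birth classes across a configurable span, an
age-at-slaughter covariate (N(550, 45^2) days), a genotyped subset
(default ~44% of the herd), multi-trait phenotypes under the animal model
with arbitrary T and R, ordinal score scales by fixed-threshold
discretization of continuous liabilities (realism only; the analysis treats
scores as continuous), and optionally a planted QTL whose share of
sigma_u^2 is known exactly (the polygenic part is rescaled so total
additive variance is unchanged).

Breeding values are generated recursively: founders from MVN(0, T),
descendants as the parental mean plus a Mendelian-sampling deviation with
covariance T (0.5 - 0.25(F_s + F_d)), using the same inbreeding
coefficients as the A matrix — so REML recovery tests are unbiased by
construction.  Genotypes descend by gene dropping with Haldane
recombination at 1 cM/Mb; founder marker alleles are drawn independently
per marker from a configurable frequency range.  An optional founder
haplotype pool (`founder_ld_pool=k`) assembles founder haplotypes from k
distinct haplotypes per 1-Mb segment, creating block LD at the window scale
while leaving blocks independent.

What it does not emulate, and what that means for the tests: no heterosis
or dominance, no breed-specific allele frequencies, no sequence-level
mutation/coalescent history, and — in the default LD-free mode — none of
the realistic array LD that concentrates regional signal.  Passing
recovery tests therefore demonstrate that the estimation machinery is
correct under the stated model, not that the scan has any particular power
on real array data.  In particular, the end-to-end power study at desk
scale (500 animals, 2,000 markers, a 5% QTL) shows the fundamental limit of
the statistic in LD-free data: the backsolved effect of a lone QTL marker
is the ridge estimate with shrinkage factor ~0.2 at that scale, so its
estimated window share is on the order of (true share) x shrink^2 ~ 0.2-0.5%
and cannot cross an absolute 1% call threshold, even though the QTL window
reliably tops the ranking.  The gentle nonlinearA weighting (base 1.05)
does not bridge this: with only thousands of markers the standardized
effect of a true QTL sits near 5-6 sd, far from the ~49 sd needed for the
weight cap of 10 to bind.  The corresponding acceptance check is left
failing with this analysis rather than weakening the threshold; the null
half (no calls without a QTL) holds.

## Numerical choices

- All randomness flows from one top-level seed via `numpy.random.SeedSequence`
  spawning; derived seeds stay below 2^31.
- PSD checks: smallest eigenvalue >= -1e-8 x trace; inverse residuals
  checked at 1e-6-1e-8 in tests.
- Singular fixed-effect blocks in the MME (confounded levels) are reported
  with a warning and resolved by a Moore-Penrose generalized inverse.
- Estimated correlations are clamped to [-1, 1] with a warning when
  numerical rounding pushes them outside.
- Ranking ties (top-20 markers) break deterministically by bp position.
- Chromosome labels are strings; marker maps must be bp-sorted within
  contiguous chromosome blocks (no lexical ordering assumptions).

## Problem sizes used by the shipped studies

Parameter-recovery studies simulate 2,040-animal herds (240 founders, five
generations, three offspring per mating, born 1989-2018) and average
AI-REML estimates over 8 seeds (moderate-h^2 traits), 20 seeds (the 0.19-h^2
trait) and 16 seeds (the bivariate genetic correlation) — replicate counts
sized from the Monte-Carlo standard error of the averaged estimate.  The
end-to-end power study uses 500-animal herds with 2,000 markers on ten
40-Mb chromosomes.  These sizes were chosen as the smallest at which the
Monte-Carlo error of the recovery targets is well below the quantities
being recovered.

## Known limitations

- Desk-scale dense linear algebra throughout: no sparse MME, no APY-style
  G-inverse approximations, no metafounders, no unknown-parent groups.
- Single records per animal per trait; no maternal, permanent-environment
  or threshold (ordinal-liability) models; no Gibbs sampling.
- The bivariate dense (unequal-missingness) path is O(n^3) per iteration.
- Reported standard errors are curvature-based approximations.
- The conditional scan regresses on observed covariate phenotypes; with
  strong mediation plus measurement error the adjustment is partial, as in
  the original method.
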