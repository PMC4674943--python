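# Methods

This note documents the models, algorithms and design choices behind
`vargwas`, in the order the pipeline runs them.

## Pedigree and relationship structure

Additive relationships follow the standard numerator relationship matrix A
with diagonal 1 + f. Inbreeding coefficients are computed by recursive
path tracing over Mendelian-sampling variances (each animal's
self-relationship is accumulated as Σ l² d over its ancestors), so the
dense A is never materialized for f alone; the dense tabular recursion is
kept for desk-scale use and as the oracle in the tests. The mixed models
consume the sparse A⁻¹ assembled from Henderson's rules, and
log|A| = Σ log d_i from the same decomposition. Unknown parents are draws
from an unrelated, non-inbred base population. Pedigree depth truncation
is available but off by default.

## Phenotype editing

Counts below 4 are discarded (recording artefacts and non-viable litters),
counts of 27 or more are capped at 27, and parities of 10 or more are
pooled into one class. Editing is idempotent. For the sow-level bivariate
analysis, only sows with ≥ 3 (edited) litters enter, the log of the
unbiased (n−1) sample variance is used, and sows whose litters are all
identical are excluded — a zero sample variance has no log and carries no
usable dispersion information.

## The mixed-model engine

One engine serves every fit: one- or two-trait Gaussian mixed models with
categorical fixed effects (intercept + treatment coding), random terms
driven by A or by identity, per-observation residual weights
(var(e_ti) = σ_et²/w_ti), and — for the sow-level bivariate analysis —
a 2×2 correlated residual per sow. Two-trait random terms carry a full
2×2 covariance matrix S_k, so G_k = S_k ⊗ K_k and G_k⁻¹ = S_k⁻¹ ⊗ K_k⁻¹.

REML maximizes the restricted likelihood directly,

    -2 l_R = log|R| + log|G| + log|C| + y'Py,

with log|C| from a sparse LU factorization (SuperLU, symmetric-mode
minimum-degree ordering) of the mixed-model equations. The search runs on
an unconstrained scale (log variances, atanh correlations) with a compact
BFGS using forward-difference gradients; the inverse-Hessian approximation
can be warm-started across related fits, which the DHGLM loop exploits.
A soft quadratic barrier beyond |atanh r| = 3 (|r| ≈ 0.995) keeps flat
likelihoods from running into the correlation boundary. Convergence is
declared when the relative change of the restricted log-likelihood falls
below tolerance (default 1e-8) on consecutive steps; an optional
Nelder-Mead polish tightens the optimum to ~1e-8 relative for closed-form
comparisons. Variances are floored at 1e-8 (boundary components pin
there). Approximate standard errors come from a central finite-difference
observed-information matrix on the natural (variance/covariance) scale,
with delta-method SEs for the implied correlations. Singular
fixed-effect structures are detected from near-zero LU pivots and reported
as rank errors naming the factors involved.

Leverages h_i = [W C⁻¹ W' R⁻¹]_ii are computed from a selected inverse of
C on the columns a trait actually uses (unit-vector solves against the
cached factorization, chunked); Σ h_i equals the effective number of
parameters. The same machinery yields prediction-error SEs of EBVs and
the cluster self-influence used below.

### The conventional bivariate analysis

Sow-level responses (meanTNB, log var TNB) share one fixed
farm-year-season factor, an additive pair with S_a ⊗ A, and a correlated
2×2 residual per sow. The residual weights are n_litters for the mean and
(n_litters−1)/2 for the log variance — the reciprocals of the approximate
sampling variances of a mean and of a log sample variance. There is no
permanent-environment term: each sow contributes a single record per
trait, so the residual correlation carries all non-genetic covariance.

## The DHGLM

The dispersion part treats log(e²/(1−h)) — a log-χ²₁ quantity — through
its first-order linearization around the current predicted residual
variance s2:

    psi_i = log s2_i + (e_i²/(1−h_i) − s2_i)/s2_i .

The bivariate REML fit of (y, psi) uses weights w = exp(psi_hat)⁻¹ for the
mean part and w_v = (1−h)/2 for the dispersion part, with two residual
scaling variances expected to converge to ≈ 1. After each fit, residuals,
leverages, the dispersion predictor, psi and the weights are refreshed;
the loop stops when every component (including the scalings) changes by
less than the tolerance (default 1e-6 relative).

Design choices that stabilize and de-bias the fixed point:

* **Initialization.** The univariate mean-trait REML fit supplies starting
  components, residuals and leverages; s2 starts at the homoscedastic
  σ_e², so the first psi is the classic deviance response.
* **Relaxation.** The raw fixed-point iteration alternates between two
  states (the dispersion intercept and the mean-part scaling chase each
  other); averaging successive log-variance predictions (factor 0.5)
  removes the two-cycle, and an Aitken-style vector extrapolation of the
  slow remaining geometric mode cuts the iteration count roughly in half
  (desk scale: ~18–22 iterations to 1e-6).
* **Cluster-jackknifed dispersion predictions.** The prediction
  s2 for a sow's observations contains her own permanent dispersion
  effect, which is partly fitted to her realized χ² noise. Feeding that
  prediction back into psi deflates the within-sow variance of the
  working response, which in turn understates the sampling noise of the
  sow means and inflates the permanent dispersion variance (and pulls the
  dispersion scaling visibly below 1; we observed 0.7 where 1 is
  expected, and a ~50 % inflation of σ_pev² against an exact-likelihood
  oracle). Each sow's prediction is therefore deflated to its
  leave-own-sow-out value using the closed-form smoother identity
  ψ̂⁽⁻ᵏ⁾ = ψ̂ − S_k(ψ̄_k − ψ̄̂_k)/(1−S_k), where S_k is the sow's
  self-influence computed from the influence matrix. With this
  correction the scalings sit at 1.0 within a few percent and σ_pev² is
  recovered (checked against exact maximum likelihood by 2-D
  Gauss-Hermite quadrature on a pedigree-free variant of the model).
  The correction can be switched off (`jackknife_clusters=False`).
* **Partial inner fits.** Each outer iteration runs a few warm-started
  quasi-Newton steps rather than a full REML convergence; the joint fixed
  point (components, weights, psi) is the same, and a final fully
  converged fit with standard errors closes the run. Influence
  quantities are refreshed on a schedule once the weights settle.

The reported summaries are the component table with SEs and correlations,
GCV_SDe = σ_av/2 (the proportional change of the residual SD per genetic
SD), and the squared-phenotype heritability
h_v² = σ_av²/(2σ_P⁴ + 3(σ_av² + σ_pev²)), a reliability-type measure.
Evaluating that formula with desk-scale components on the log scale gives
values of order 10⁻⁴–10⁻³; published analyses sometimes print larger
values, which the formula as stated does not reproduce — the operation
implements it literally and the discrepancy is left visible.

Dispersion-part EBVs stay on the natural-log variance scale; any mapping
to SD scale goes through GCV-style transforms only.

A sensitivity study pins the permanent-environment covariance at zero on
data generated with r_pe = −0.8 and r_a = +0.5: the additive covariance
then has to absorb the strong negative non-genetic mean-variance
association and the estimated genetic correlation flips sign. The effect
requires moderate family sizes (half-sib groups of ~8 in the test): with
very large half-sib families the additive covariance is determined by
between-family contrasts and simply refuses the sow-level covariance
rather than flipping.

## Deregression

EBVs from two univariate re-fits at the final DHGLM weights (one per
trait, so neither trait's proof is leaked into the other through the
covariances) are deregressed by the two-effect (parent average,
individual) information partition documented in `vargwas.deregression`:
reliabilities from r² = 1 − s²/((1+f)σ_a²), closed-form information
contents, removal of the parent average, and weights
w = (1−h²)/((c + (1−r²_d)/r²_d)h²). The marker-incompleteness fraction c
defaults to 0.5 and is configurable; the applied value is echoed in the
output metadata. Animals whose own-plus-progeny information is
non-positive are dropped and reported. The reliability filter keeps
records with r² ≥ 0.05 (boundary inclusive). For the dispersion trait the
single-record heritability on the working-response scale,
σ_av²/(σ_av² + σ_pev² + 2), sets λ; the sampling variance of the working
response is ≈ 2.

## Genotype QC

SNP filters run quality score → sex chromosome/unknown position → MAF, in
that order, with per-rule counts reported; animal filters run call rate
first, then the opposing-homozygote inconsistency rate against genotyped
parents (threshold 0.01 of compared loci — "many inconsistencies" needs a
number; it is configurable). MAF is computed on retained animals.
Missing calls surviving QC are mean-imputed (2p) for the association
design. The sex-chromosome filter is unconditional on the chromosome
label set {X, Y, MT, 23}.

## Bayesian variable selection

Per cycle the sampler updates, for every SNP, the mixture indicator with
the effect integrated out (conjugate normal algebra) and then the effect
from its conditional; the intercept is Gibbs-updated; σ_g1² and σ_e² move
by random-walk Metropolis-Hastings on the log scale with step 0.003
(0.004 in the sensitivity configuration). Because that step is small by
design, the variances cannot travel far during a scaled-down run, so
during burn-in only they are refreshed from their conjugate conditionals
(Jeffreys-style draws, with σ_g1² floored at 2σ_g0²); after burn-in the
kernel is exactly the stated MH sampler. σ_g0² is fixed at 1e-4 of the
initial σ_g1², which itself is set so that pi1 × (number of SNPs) average
large effects would carry 30 % of the response variance. Dosages are
centered; the intercept absorbs the centering. Posterior summaries are
running averages (inclusion fraction, posterior-mean effect); the
deviance is stored per cycle for the Gelman-Rubin diagnostic (two or more
chains; R̂ < 1.1 declares convergence; values marginally below 1 from the
(n−1)/n factor are floored at 1).

Percentages of genetic variance default to the denominator
Σ_j 2p_j q_j β̄_j² over all SNPs; a total genetic variance from the DHGLM
can be supplied instead. The per-chromosome summary splits variance into
the strata BF ≥ 30, 10 ≤ BF < 30, BF < 10.

## Synthetic data

The generator draws (a, a_v) down the pedigree by bivariate Mendelian
sampling (exactly S_a ⊗ A), iid bivariate (pe, pe_v) per sow, fixed
parity effects with the usual rise-then-decline profile, normal
farm-year-season effects (SD 0.3), and residuals e_ij ~ N(0, exp(η_i))
with η_i = μ_v + a_v,i + pe_v,i, where μ_v is set so that E[exp η] equals
the target mean residual variance (6.5 by default). Genotypes are
gene-dropped founder alleles at frequencies uniform in the MAF range;
planted mean-QTL and vQTL add centered dosage effects to a and a_v, with
the polygenic variances reduced by the planted genic variance so totals
stay nominal (QTL effects are independent of the polygenic correlations).
Phenotypes are continuous by default — the analysis model is Gaussian —
with an integer rounding/truncation mode to exercise the editing rules.
All randomness flows through a single PCG64 generator per call, so every
dataset is reproducible cross-platform from its seed.

Default scale ("desk preset"): 50 founder sires + 400 founder dams, 2,000
phenotyped sows with 5 parities each, 25 farm-year-season classes, and
the generating parameters σ_a² = 1.2, σ_av² = 0.05, r_a = +0.5,
σ_pe² = 0.7, σ_pev² = 0.15, r_pe = −0.8. These sizes keep a full DHGLM
fit (including SEs) in the 5–7 minute range on one CPU while leaving the
components identifiable; the GWAS studies use 500 animals × 2,000 SNPs ×
20,000 cycles. What the generator does *not* emulate: linkage
disequilibrium from recombination maps, selection over generations,
non-Gaussian litter-size tails, and cross-fostering — so passing tests
demonstrate correct inference under the model's own assumptions, not
robustness to real-data violations of them.

## Known limitations

* The linearized DHGLM is an approximate-likelihood method; even with the
  cluster jackknife its dispersion-part correlations carry more sampling
  variability than the observed-information SEs suggest at a few records
  per sow, and estimates of r_pe scatter visibly between replicates.
* The observed-information SEs are conditional on the converged working
  response; they do not propagate the uncertainty of the linearization
  itself.
* REML fits with many (> ~10⁴) equations rely on SuperLU fill-in staying
  moderate; deep, highly inbred pedigrees may need a better ordering.
* The MH variance moves mix slowly by construction (step 0.003); runs
  much shorter than the default 500,000 cycles lean on the burn-in
  adaptation for scale.
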