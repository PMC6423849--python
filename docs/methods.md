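# Methods

## Model

Let m SNPs be tested in each of D = 2 studies. The joint hypothesis states
(H₁ⱼ, H₂ⱼ) form a stationary, irreducible, aperiodic Markov chain over the
Cartesian product space {0,1}², serialised in the fixed order
(0,0), (1,0), (0,1), (1,1) (state index u = Σᵢ bitᵢ·2ⁱ with i the zero-based
study index). The engine is written for general D (2^D states); D = 2 is the
default and the only configuration with a canonical null subset. For D > 2
the null subset is configurable because more than one partial-conjunction
null is defensible ("associated in at most one study" vs "in at most D−1");
no default semantics are claimed beyond the complement of the all-ones
state.

Given the states, z-values are conditionally independent with null density
N(0,1) — fixed, never estimated — and alternative density N(μᵢ, σᵢ²) per
study. z-values come from the one-sided transform z = Φ⁻¹(1 − p); p-values
recorded as exactly 1 are set to 0.99 first (keeps z finite at −2.33), and a
configurable floor ε = 1e-15 is applied at the small end (z ≈ 7.94) so the
transform never produces ±∞. The floor matters only for genome-wide
significant hits whose exact magnitude beyond z ≈ 8 carries no additional
ranking information in this model.

repLISⱼ, the posterior probability that SNP j is associated in at most one
study, is computed by the forward-backward algorithm. The recursions are
run in their per-site normalised (scaled) form: forward rows are normalised
to sum to one, the per-site normalisers cⱼ are stored, log-likelihood is
Σ log cⱼ, and the backward recursion shares the same constants so that
γⱼ ∝ αⱼβⱼ is well scaled at any m. Reported forward/backward variables are
therefore scaled; the unscaled quantities are recoverable as
αⱼ·Πₖ≤ⱼcₖ and βⱼ·Πₖ>ⱼcₖ. A length-1 input is legal: the chain contributes
only π. Repeated 4-state matrix-vector inner loops are compiled with numba;
the emission matrix, pairwise posteriors and M-step are vectorised numpy.

Numerical tie-breaking throughout (step-up ordering, top-k selection, ROC
construction) uses stable sorts with the original site index as the
tie-breaker, so results are deterministic across platforms. Posterior null
masses are clipped to [0,1] against few-ulp roundoff before the decision
rule.

## Estimation

EM with closed-form M-steps: π ← γ₁; A\_uv ← Σξⱼ(u,v)/Σγⱼ(u); μᵢ and σᵢ²
are posterior-probability-weighted means/variances with weights
pᵢⱼ = P(Hᵢⱼ=1 | Z). Choices the update formulas leave open:

- **Stopping**: relative log-likelihood change < 1e-6, at most 500
  iterations. At m = 10000 the fit typically converges in ~10 iterations.
- **Initialisation**: `fixed` (π uniform, A with 0.7 diagonal, μ = 2,
  σ = 1; the default), `moment` (μᵢ = mean of the upper quartile of study-i
  z), or `random` (seed-jittered fixed values). `n_restarts` counts total
  runs; runs after the first use jittered random starts and the best final
  log-likelihood wins. EM on this likelihood can reach local optima;
  restarts are the mitigation. The default is a single run from the fixed
  start, which was reliable across the simulation designs.
- **Identifiability**: μᵢ is clipped at 0 (`mean_sign_constraint`, default
  on). The one-sided p→z transform makes true signals right-shifted, and
  the constraint prevents the null and alternative components from swapping
  labels. Monotone ascent is preserved because the clip is the constrained
  M-step maximiser.
- **Degeneracy guards**: σᵢ floored at 1e-3 (prevents component collapse
  onto a single point); a transition row with zero posterior mass is reset
  to uniform with a logged warning.

The independence-restricted variant (`independence=True`) constrains every
transition row to equal the state frequencies, which is exactly the EM for
an i.i.d. four-group mixture. It serves as the chain-free empirical-Bayes
baseline in the comparisons.

## Decision rules

The step-up rule rejects the l smallest statistics where l is the largest t
whose running mean of sorted repLIS values is ≤ α; l = 0 when even the
smallest exceeds α. δⱼ = 1 claims association in both studies, and the FDR
is the expected false proportion among those claims. The BH baseline applies
the standard step-up to the per-site maximum of the two p-values.

For multi-chromosome data the model is fitted per chromosome (chains do not
cross chromosome boundaries; within a chromosome, SNPs are ordered by
position, 1-based as in standard summary files) and the repLIS values from
all chromosomes are pooled before the single step-up cutoff, so ranking is
genome-wide. A top-k mode replaces the α cutoff for exploratory real-data
use where the nominal level for a short list is not the quantity of
interest. Strand/allele harmonisation is out of scope: p-values are
strand-agnostic.

## Synthetic data

The generators emulate two study designs:

- **Independent tests**: joint states i.i.d. multinomial with cell
  probabilities (0.4, 0.2, 0.2, 0.2); σ₁ = σ₂ = 1, μ₂ = 4, μ₁ varied over
  {2.0, 2.5, 3.0}.
- **Locally dependent tests**: four-state chain with uniform initial law,
  transition diagonal 0.7 and off-diagonal 0.1 (the (1,1) row is
  (0.1, 0.1, 0.8−a, a) with self-transition a = 0.7 by default); σ = 1,
  μ₂ = 2, μ₁ varied over {3, 4, 5}.

Both use m = 10000 sites, 200 replications and nominal level 0.1 by
default. Replication r draws from the child stream SeedSequence([seed, r]),
so experiments are bit-reproducible and all procedures see identical data
within a replication. An optional second-order transition tensor lets the
generator produce order-2 chains analysed with the (misspecified) order-1
model.

Metrics: FDR is the mean false-discovery proportion over replications (0/0
→ 0); FNR is the false-nondiscovery proportion among non-rejections, the
standard dual of FDR in the local-index-of-significance literature (the
source analyses report FNR without displaying a formula; this
operationalisation is ours), also with 0/0 → 0; ATP is the mean count of
correctly rejected replicated signals. Monte-Carlo standard errors over
replications are reported and all stochastic test tolerances are set at 3
SEs. ROC curves sweep "reject iff statistic ≤ c" over unique statistic
values (positives = (1,1) sites); tied sites enter together.

A genotype-level generator supports sensitivity-at-top-k evaluation with
realistic local correlation: haplotypes copy the previous SNP's allele with
probability ρ (default 0.9) or redraw from the allele frequency (uniform on
[0.05, 0.5]); genotypes are haplotype sums; disease status follows
logit P(Y=1|G) = β₀ + Σᵢ βᵢ Gᵢ over six causal SNPs with β₀ = −8 and
βᵢ = log 2; cases and controls are accumulated by rejection sampling; each
SNP is tested with a Cochran-Armitage trend test. Disease prevalence under
these coefficients depends on the realised allele frequencies (roughly
0.3–1%), so prevalence-sensitive quantities are approximate. This
generator produces block-correlated signals, not the full LD structure of
real reference haplotypes.

What the simulations do not emulate: real LD block structure, allele
frequency spectra, population stratification, study-specific genomic
inflation, or the genotype-level QC of a real analysis. Passing tests
demonstrate the procedure's operating characteristics under the stated
generative models, not on real GWAS data.

## Validation scales and known limitations

Exact checks (forward-backward vs full-state-sequence enumeration, step-up
vs exhaustive threshold scan, independence-chain closed form) run at m ≤ 6
with 4^m enumeration and at 1e-10/1e-12 tolerances. FDR-control checks run
at the full published scale, m = 10000 with 200 replications; the
procedure-comparison and ranking checks use 50 replications, which is ample
for the large effects involved.

With the EM implemented here, the data-driven procedure's worst-case
empirical FDR over the independent-tests grid comes out ≈ 0.101 at nominal
0.1 — mildly anticonservative and in line with the asymptotic validity of
the plug-in statistic, since at m = 10000 the EM estimates are nearly
exact and the plug-in statistic is nearly the oracle statistic.

Other limitations: the chain is homogeneous (no position-varying transition
probabilities, no Markov random field); emissions are single Gaussians per
component (no heavier-tailed alternatives); no standard errors for the EM
estimates; D ≥ 3 is supported by the engine but the computation grows as
4^D per site pair and the null-subset semantics must be chosen by the user.
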