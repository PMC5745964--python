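# Methods

## Model and estimation chain

The package implements marker-effect estimation for `y = 1 mu + X b + e`
with standardized genotypes (`X'1 = 0`, so `mu_hat = mean(y)` decouples from
the marker equations and is never re-estimated downstream).  Three
estimators share one SVD of `X`:

1. **SNP-BLUP.**  All effects `b_j ~ N(0, sigma_b^2)` with
   `sigma_b^2 = sigma_g^2 / k`.  In component space the mixed-model
   equations are diagonal, so the solve is `O(m)` after the `O(N^2 k)` SVD.
2. **Direct BayesC.**  Mixture prior: `b_j ~ N(0, sigma^2)` with
   probability `pi`, else `b_j = 0`.  Per-SNP evidence is recovered from
   the SNP-BLUP fit alone: effective information
   `c_j = sigma_e^2/PEV_j - lambda_b`, right-hand side
   `rhs_j = (c_j + lambda_b) b_hat_j`, then the likelihood ratio, posterior
   probability, and variance weights `D~_j` (rescaled to sum to `k` so the
   total prior variance matches SNP-BLUP).  One symmetric positive-definite
   `m x m` solve gives the BayesC component effects.
3. **MCMC BayesC.**  The comparison standard: single-site Gibbs with
   inclusion indicators, fixed variances, systematic scan, incremental
   residual updates (refreshed from scratch every 500 sweeps; the recorded
   drift is a correctness diagnostic).  Posterior-mean effects and
   inclusion frequencies are the outputs.

Key assumptions: variances (`sigma_g^2`, `sigma_e^2`) and the prior
parameters (`pi`, `sigma^2`) are known, not estimated; the single-SNP
residual covariance `R = I + G_{-j}/sigma_e^2` is treated as independent of
`j` (it is never formed — the method reaches it only through the PEV); and
the BayesC solution is a *linear-model* approximation that translates
posterior probabilities into per-SNP variances rather than model-averaging.

## PEV and the null space

The textbook component-space PEV quadratic form omits the loading a SNP has
outside the retained components, which is non-zero whenever `k > N` or after
truncation.  The implementation adds that mass at the prior variance:

    PEV_j = sigma_b^2 (1 - ||V_j.||^2) + sum_i V_ji^2 sigma_e^2 / (S_i^2 + lambda_b).

This makes the PEV equal to the dense MME-inverse diagonal exactly at full
rank, reduces to the quadratic form when `||V_j.|| = 1`, and guarantees
`0 < PEV_j <= sigma_b^2`, so the downstream information recovery
`c_j = sigma_e^2/PEV_j - lambda_b` is finite and non-negative (a SNP with no
loading on any retained component reports `c_j = 0`, i.e. no information,
rather than a division by zero).

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| `pi` | prior QTL probability | 0.01 | number of QTL / number of SNPs in the validation design; tune by hold-out (`holdout_tune`) in real data |
| `sigma^2` | slab variance | `0.001 sigma_g^2` | the largest variance a single SNP effect is expected to explain; `slab_mode="pi_consistent"` instead sets `sigma_g^2/(k pi)` so the mixture's total variance matches `sigma_g^2` |
| `frac` | per-chromosome SVD truncation | 0.95 | fraction of `Trace(S^2)` retained; an absolute `max_components` cap is also available |
| PP floor | lower bound on PP before weighting | 1e-6 | keeps `V'DV` positive definite; results are insensitive below ~1e-4 |
| component cap | maximum merged components | 10 000 | the `m x m` weighted solve is dense; beyond this, truncate harder |

Degenerate inputs: monomorphic SNPs are rejected at standardization (filter
on MAF first); if the Cholesky of `V'DV` fails, one retry adds a jitter of
`1e-10 mean(diag)` and logs it; `pi = 1` is allowed everywhere and collapses
BayesC onto SNP-BLUP when `sigma^2 = sigma_b^2` (a test exploits this).
SVD sign ambiguity is harmless: all outputs are invariant to matched column
sign flips, which the tests assert rather than enforcing a convention.

## Simulator

The generator emulates a livestock-like population: Wright's idealized
structure (random union of gametes with replacement, non-overlapping
generations, hermaphroditic, selfing allowed), Poisson recombination
(1 Morgan per chromosome), infinite-sites mutation at integer base-pair
positions, a long historical phase to reach mutation-drift equilibrium, one
expanded reference generation carrying phenotypes, and ten descendant
generations at reduced effective size to mimic the drift of a breeding
nucleus.  True breeding values are `TBV = alpha X t` with `t` standard
normal at the causative SNPs and `alpha` fixing `Var(TBV) = 1` in the
reference; phenotypes add `N(0, (1-h2)/h2)` noise.

Full-scale defaults reproduce the validated design (20 chromosomes x 1e8 bp,
Ne 1000 for 10 000 generations, reference of 10 000, mu = 1e-8/bp, 200 QTL
per chromosome, h2 = 0.5, forward Ne 100); they are cluster-scale.  The desk
preset used throughout the tests and the acceptance script keeps the same
architecture at laptop size: 2 chromosomes x 1e6 bp (still 1 Morgan each),
Ne 100 for 1000 generations (= 5 coalescent time units, enough to approach
equilibrium), reference of 500, 20 QTL per chromosome, forward Ne 50, and
mu = 1e-6/bp — chosen once so that theta = 4 Ne mu L = 400 per chromosome
gives a SNP density regime comparable to full scale (a few thousand
MAF-eligible SNPs genome-wide).

What the desk scale does *not* emulate: the `k >> N` regime of real sequence
data (desk k/N ~ 6 versus ~53 at full scale), long-range LD across 100 Mb,
and the 531k-SNP memory pressure that motivates the per-chromosome SVD in
the first place.  Passing tests therefore validate the algebra, the
statistical calibration and the qualitative behaviour (accuracy decay,
method parity, QTL enrichment), not full-scale performance numbers.
Descendant generations receive no new mutations by default
(`mutations_in_forward`): new variants are absent from the reference panel
and would carry zero estimated effect.

## Design choices that were genuinely open

- **Information recovery uses `lambda_b`, not `lambda`.**  The right-hand
  side is reconstructed by inverting the *SNP-BLUP* normal equation that
  produced `b_hat_j`, so the SNP-BLUP ratio is the algebraically consistent
  one; with it, `c_j` and `rhs_j` are exact (not approximate) at full rank.
- **Chip thinning** picks evenly spaced SNPs per chromosome (optionally
  excluding causatives); a density-based rule would need a real array
  design, which is out of scope.
- **Watterson validity check** runs with reference size equal to the
  historical population size so the sampled haplotypes are the whole
  population and `E[S] = theta a_{n-1}` applies cleanly; the SD uses the
  no-recombination variance, an upper bound for 1-Morgan chromosomes.
- **Hold-out tuning** scores candidate `pi` values by validation accuracy
  against held-out *phenotypes* (the only observable proxy for TBV in real
  data) and reuses one SVD per training fold across the whole grid.

## Known limitations

- The direct method's QTL signals are anti-conservative in QTL-rich regions
  (it assumes the per-SNP variance is known without error), and its PP sum
  is generally far below the MCMC one; the two are reported side by side
  and never asserted equal.
- Under a correctly specified null, the mean direct PP carries a small
  positive bias (~1% relative at N=200, k=500), an intrinsic footprint of
  treating `R` as SNP-independent; it is invisible at any practical
  tolerance but measurable under heavy replication.
- Bias (regression of TBV on GEBV) deviates from 1 at desk scale —
  over-shrunk effects push it above 1 — and is reported, not corrected.
- Variance components are never estimated (no REML, no variance sampling in
  the Gibbs option shipped here); `pi`/`sigma^2` tuning is a plain hold-out,
  not a formal cross-validation scheme.
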