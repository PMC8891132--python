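# Methods

This note documents the statistical models implemented in `csbayes`, the
choices made where the original analysis left details open, and what the
synthetic-data generator does and does not emulate.

## Cohort model and mutation classification

A patient record carries two *CSB/ERCC6* mutation descriptors (biallelic
requirement), a clinical subtype label, sex, onset age in months and a
source tag.  Mutations are located on the 1-based HGVS c. coding coordinate
system; no genomic liftover is attempted.

Classification relative to the PGBD3 insertion (c.1397+6912, intron 5):

- exonic positions ≤ 1397 (coding exons 2–5) are UPSTREAM; ≥ 1398
  (exons 6–21) are DOWNSTREAM;
- variants inside intron 5 are split at the insertion coordinate itself
  (c.1397+N is UPSTREAM for N ≤ 6912, DOWNSTREAM for N > 6912; c.1398−N is
  DOWNSTREAM) and always carry a review flag, because the exon-based
  dichotomy does not address them — the flag makes these records easy to
  audit rather than silently committing to either side;
- other intronic variants follow their exonic anchor;
- a precomputed region label is accepted as-is, and cross-checked against
  the coordinate when both are present.

Pairs map to the three genotype groups {U,U}→2U, mixed→1U1D, {D,D}→2D,
symmetric in allele order.  Variant classes are taken from the input (the
package deliberately does not infer PTV/PAV from HGVS strings; an opt-in
keyword helper maps nonsense/frameshift/splice→PTV, missense/in-frame→PAV).
A PTV+PAV pair is analyzed in the PAV group — the more permissive allele
dominates.  Subtype labels "I or II", "I/II" and unclassified records are
excluded from ordinal analyses with a per-record reason log; COFS is pooled
into type II before any tabulation.  Severity is ordered III < I < II with
integer codes 1 < 2 < 3.

## Dirichlet contingency analysis

The 3×3 genotype × severity table is one multinomial over nine cells with a
conjugate Dirichlet(α) prior, so the posterior is Dirichlet(counts + α).
Defaults: Jeffreys α = 0.5 per cell (a uniform α = 1 option is retained);
any α > 0 handles zero cells without continuity corrections.  200 000
Monte-Carlo draws (Monte-Carlo SE on Pr(OR>1) ≈ 0.1 percentage points)
give draw-wise odds ratios for any contrast of two disjoint (possibly
pooled) row sets and two severity columns; pooling rows before or after the
posterior is immaterial by Dirichlet aggregation.  Summaries are the
posterior **median** OR, the equal-tailed 95% credible interval and
Pr(OR > 1).  The median (rather than the ratio-inflated mean) is pinned
down by an independent oracle: E[log p] under a Dirichlet is
ψ(α_cell) − ψ(α_total), so the posterior mean log-OR is a four-term digamma
sum; the tests verify the sampled mean matches it on all nine contrasts
(≤ 0.01) and that the median agrees with it wherever cell counts are
moderate.  For the small type-III cells (1–3 patients) the log-OR posterior
is visibly skewed and median and mean separate by up to ~0.1 — an inherent
feature of the posterior, not a sampler artifact.

## Proportional-odds severity regression

The central model is a cumulative-logit (proportional-odds) regression on
the ordered severity Y ∈ {III < I < II}:

    logit P(Y ≤ k | x) = θ_k − x′β,   k = 1, 2,   θ₁ < θ₂,

so β_j > 0 means higher odds of a *more severe* subtype and e^{β_j} is the
clinically reported odds ratio.  Covariates are dummy-coded with 2U as the
position reference and PAV as the variant-class reference; the multivariate
model adds both factors additively (no interaction).  The likelihood is
computed from sufficient-statistic counts (strata × severity), which makes
fitting from the aggregate table and from expanded per-patient records
identical by construction and keeps each evaluation O(strata).

Priors on each coefficient are Normal on the log-OR scale, elicited from a
central 95% OR range (L, U): μ = (ln L + ln U)/2, σ = (ln U − ln L)/(2z),
z = 1.95996.  Built-in priors: vague N(0, 1000); precise N(0, 0.674)
(OR ∈ [0.2, 5]); optimistic N(1.099, 0.377) (OR ∈ [0.9, 10]); and
N(0.661, 0.234) (OR ∈ [0.75, 5]) for the PTV-vs-PAV analysis.  Elicited
values are rounded to 3 decimals, matching how they are conventionally
quoted.

Cutpoints are kept ordered by the reparametrization θ₂ = θ₁ + e^δ, with
diffuse N(0, 1000) priors on θ₁ and δ.  This choice is dominated by the
data at n = 136: the same fit run through an independent Gibbs engine
(JAGS, sorted flat-prior thresholds) agrees with the package's sampler to
two decimals on every coefficient, and an informative N(0, 1) threshold
prior was checked and rejected — it *moves* the position effect rather than
merely diffusing it.

### Relation to the originally reported estimates

On the packaged table the vague-prior fit gives OR(2D vs 2U) = 2.3
[0.9–5.6], Pr(OR>1) = 96.5%, and OR(1U1D vs 2U) = 0.9 [0.3–2.8], Pr = 40.8%;
the optimistic prior gives OR(2D) = 3.0 [1.5–5.9], Pr = 99.9%.  The
1U1D estimates and all Dirichlet/elicitation quantities reproduce the
originally reported values at print precision, but the original 2D point
estimates were reported lower (2.0 vague, 2.6 optimistic).  Three
independent routes — this package's Metropolis sampler, a JAGS Gibbs fit of
the identical model, and the frequentist maximum-likelihood estimate
(β₂ = 0.815, OR 2.26) — agree with each other and not with those two
printed values, and the gap is a uniform shift of the 2D coefficient only,
across all priors, which no defensible cutpoint-prior choice reproduces.
The package therefore reports what the stated model computes from the
published table, without adjustment.

## Group-mean onset-age model

Age at first symptoms (months) is Normal(μ_g, σ²) within each genotype
group — a categorical-predictor linear model in the ANOVA mould.  It uses a
cell-means parametrization (one mean per group) so the N(0, 100) prior
applies to each group mean symmetrically, rather than asymmetrically to a
reference mean and offsets.  The residual SD has a half-Normal(scale 50)
prior — weak relative to the observed spread of ~13 months; σ is sampled on
the log scale with the Jacobian included.  Missing ages are dropped
(complete cases); a group with no observations is reported prior-dominated
with a warning.  The decision quantity is Pr(μ_g1 − μ_g2 > 0) over joint
draws.  A `fixed_sigma` mode exists so tests can check the exact
Normal-Normal conjugate posterior.  The originally reported group means
(11.8 / 11.4 / 6.5 months) are used only as synthetic truth in recovery
tests — the raw ages behind them are not public and those numbers are not
reproduction targets.

## Sampling engine

All models share one sampler: component-wise random-walk Metropolis.
Per-parameter proposal scales adapt during burn-in only, by a Robbins–Monro
recursion on the log-scale toward 0.44 acceptance (batches of 50, gain
min(1, 5/√batch)), and are frozen afterwards so the retained chain is a
valid time-homogeneous Markov chain.  Defaults follow the study schedule:
3 chains, 5 000 burn-in, 150 000 retained iterations, thinning 3 (50 000
stored draws per chain).  Per-chain RNG streams are spawned from a single
integer seed (`numpy.random.SeedSequence`), making every run
bit-reproducible; chains beyond the first jitter their start by N(0, 0.1²).
Ordinal fits start cutpoints at the pooled empirical cumulative logits and
coefficients at 0; group-mean fits start at sample means and the pooled
log-SD.

Convergence is quantified (not just eyeballed): split-chain R-hat is
implemented in-package (cross-checked against arviz) with a warning
attached above 1.05, and bulk ESS comes from arviz.  On the replication
fits all R-hat values are below 1.01.  Intervals are equal-tailed (2.5/50/
97.5% quantiles, linear interpolation between order statistics), matching
the toolchain convention of the original analysis; no HPD intervals.

## Synthetic-cohort generator

`CohortSimSpec` defaults encode the study conditions: n = 147; group
probabilities 24/18/105; severity from the cumulative-logit model with
cutpoints (−1.96, 0.46) — the proportional-odds MLE of the published
table — and coefficients (ln 0.9, ln 2.0), the originally reported point
estimates; onset age from a Gamma matched by moments to mean 8, SD 13.4
months (shape ≈ 0.356, scale ≈ 22.4), rejection-truncated at 72 months
(the 13.4 > 8 relation rules out a symmetric family and the Gamma admits
the observed pile-up near birth); ~16.3% missing ages (24/147); ambiguous
labels injected at 10/147, only onto patients whose latent severity is I or
II (the boundary cases such labels describe); upstream alleles always PTV
(as observed — no upstream PAV exists in the cohort), downstream alleles
PAV with probability 37/92.  An optional PTV-pair effect adds a log-OR to
the severity predictor.

Per-patient substreams are spawned deterministically from the master seed,
so cohorts are reproducible and prefix-stable in n.  What the generator
does **not** emulate: real mutation coordinates or HGVS strings (region
labels only), correlation between onset age and severity class, sex-linked
effects, between-source (database vs literature) heterogeneity, and
classification error in the expert subtype labels.  Passing recovery and
coverage tests therefore demonstrates correctness of the estimation
machinery under the assumed generative model, not robustness to the ways
real cohorts violate it.

## Problem sizes used in the test suite

Replication fits (the published-table analyses) run at the full study
schedule.  Distributional checks use smaller, documented designs chosen to
keep Monte-Carlo error well below their tolerances: recovery fits and
conjugate-oracle checks run 2–3 chains × 9 000 iterations after 1 500
burn-in; the credible-interval coverage study fits 100 cohorts of n = 136
at 2 chains × 4 000 iterations; the onset-age recovery check averages
posterior medians over 5 cohorts of 2 000 patients per group so that
per-cohort sampling noise (SE ≈ 0.3 months) does not drive the outcome.

## Known limitations

- The upstream/downstream dichotomy collapses all positional information to
  one bit; within-region position effects are invisible to the model.
- Proportional odds is assumed, not tested; with three outcome levels and
  three strata the data cannot strongly discriminate partial-odds
  alternatives (non-proportional models are out of scope).
- The variant-class analysis is structurally confounded: every upstream
  allele in the cohort is truncating, so position and variant type are not
  separately identifiable for 2U patients.
- Intron-5 variants 5′ of the insertion are classified upstream by
  coordinate logic but flagged, because no observed rule covers them.
- The onset-age model ignores censoring and treats missingness as
  ignorable; no imputation is attempted.
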