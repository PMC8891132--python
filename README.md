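# csbayes

Bayesian genotype–phenotype correlation analysis for Cockayne syndrome
type B (*CSB/ERCC6*).

Cockayne syndrome (CS) spans a wide severity spectrum, ordered here as
type III (mild) < type I (classical) < type II/COFS (severe).  The
*CSB/ERCC6* gene carries the PGBD3 "PiggyBac" transposon in intron 5
(insertion point NM_000124.3:c.1397+6912).  Mutations 5′ of the insertion
abolish both the full-length CSB protein and the CSB-PGBD3 fusion protein,
while mutations 3′ of it spare the fusion protein — which is suspected to be
deleterious when full-length CSB is absent.  Each biallelic patient is
therefore classified as **2U** (both mutations upstream), **1U1D** (one of
each) or **2D** (both downstream), and the question is whether downstream
mutations carry a higher risk of a severe subtype.

`csbayes` implements the full analysis as statsmodels-style model objects:

- **Cohort handling** (`csbayes.cohort`) — HGVS c.-coordinate classification
  relative to the insertion (intron-5 variants are decided by the
  +6912 offset and flagged for review), PTV/PAV pair grouping (a PTV+PAV
  pair counts as PAV), exclusion of ambiguous subtype labels, and
  contingency-table construction.
- **Dirichlet contingency analysis** (`DirichletContingencyModel`) — the
  3×3 subtype × genotype table as one multinomial with a conjugate
  Dirichlet prior (Jeffreys α = 0.5 by default); odds ratios between any
  (possibly pooled) rows and severity columns via Monte-Carlo draws from
  Dirichlet(counts + α).
- **Proportional-odds regression** (`OrdinalSeverityModel`) — the central
  model: logit P(Y ≤ k | x) = θ_k − xβ over ordered severity, so e^β is the
  odds ratio of a *more severe* subtype.  Priors on each log-OR are elicited
  from a central 95% odds-ratio range: μ = (ln L + ln U)/2,
  σ = (ln U − ln L)/(2 z₀.₉₇₅); the study's three priors are built in
  (vague N(0, 1000), precise N(0, 0.674) ⇔ OR ∈ [0.2, 5], optimistic
  N(1.099, 0.377) ⇔ OR ∈ [0.9, 10]), with a `sensitivity_suite` that refits
  under each.
- **Onset-age model** (`GroupMeanModel`) — Bayesian cell-means ANOVA of age
  at first symptoms by genotype group, N(0, 100) priors on each mean,
  reporting Pr(μ_g1 − μ_g2 > 0).
- **Sampling engine** (`csbayes.mcmc`) — component-wise adaptive random-walk
  Metropolis, 3 chains × 5 000 burn-in × 150 000 iterations thinned by 3 by
  default, split R-hat and ESS diagnostics, bit-reproducible given a seed.
- **Synthetic cohorts** (`csbayes.synthgen`) — the study's per-patient data
  is restricted, so a generator draws cohorts from the assumed generative
  model (group simplex, cumulative-logit severity, moment-matched Gamma
  onset ages with missingness, ambiguous-label injection) for tests and
  parameter-recovery studies.  The published 3×3 table ships as a fixture
  (`load_severity_table`), together with a reconstructed 147-record cohort
  (`example_cohort`).

## Worked example

```python
>>> import csbayes as cb
>>> table = cb.load_severity_table()
>>> table.to_frame()
      II   I  III
2U     9  11    3
1U1D   5  11    1
2D    57  32    7

>>> posterior = cb.DirichletContingencyModel(table).fit(n_draws=200_000, seed=1)
>>> print(posterior.summary())
Dirichlet contingency analysis (prior=jeffreys, draws=200000, seed=1)
OR [95% CrI]; Pr(OR>1) %
  2D vs 1U1D, II vs I            3.9 [1.3-12.8]; 99.3
  ...
  2D vs 2U, II vs I              2.2 [0.8-5.8]; 94.1
  ...

>>> model = cb.OrdinalSeverityModel.from_table(table, priors=cb.PriorSpec.vague())
>>> result = model.fit(cb.McmcSettings(seed=1))
>>> print(result.summary())
Bayesian proportional-odds regression of CS severity (III < I < II)
priors: 1U1D~N(0,1000), 2D~N(0,1000)
chains=3 burn_in=5000 iterations=150000 thin=3 seed=1
coefficient  OR [95% CrI]; Pr(OR>1) %   R-hat
  1U1D        0.9 [0.3-2.8];  40.8   1.000
  2D          2.3 [0.9-5.6];  96.5   1.001
```

Reading the output: patients with two downstream mutations (2D) have 3.9
times the odds (95% CrI 1.3–12.8) of type II rather than type I disease
compared to 1U1D patients, and the regression puts the odds ratio of a more
severe subtype for 2D vs 2U at 2.3 with a 96.5% posterior probability of
exceeding 1 — evidence in the direction of the PiggyBac hypothesis, with
wide uncertainty.

The same analyses are available from a shell:

```sh
csbayes analyze --fixture severity_table --analysis all --seed 1 --out reports/
csbayes simulate --n 147 --seed 7 --out sim/
csbayes age --input sim/synthetic_cohort.csv --seed 2 --out reports/
```

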