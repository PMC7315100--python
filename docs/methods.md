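# Methods

## Model and procedure

The package tests each main effect and interaction of a within-subject
factorial design with its own regression, independently of every other
effect. Design cells are enumerated with the first factor varying slowest
(the data matrix must follow the same nesting). Effect codings are
{-1, 0, +1} contrast matrices: for a factor with $l$ levels, $l - 1$
columns contrasting each later level against the first; interaction
columns are elementwise products of the involved factors' columns,
enumerated with the last factor's contrast index varying fastest. These
codings span the full between-cell space: summed over all $2^K - 1$
effects the column counts add up to (number of cells) − 1.

For one effect with coding matrix $X$ (cells × $p$):

1. every subject's row is mean-centered and projected onto the column
   space of $X$ (orthogonal projection via pseudoinverse, so
   non-orthogonal codings and arbitrary invertible recodings of the same
   effect give identical results);
2. the reduced matrix is stacked column-under-column into a vector of
   length $N \cdot \text{cells}$, the coding columns are replicated per
   subject, all columns centered, and the outcome regressed on them with
   no intercept (the contrast space is symmetric around zero, so an
   offset would be meaningless);
3. $F = (SS_M/p) / (SS_E/((N-1)p))$, partial
   $\eta^2 = SS_M/(SS_M+SS_E)$. When $p > 1$ the Greenhouse–Geisser
   epsilon multiplies both degrees of freedom before the F-distribution
   lookup; a 1-df effect needs no sphericity assumption and gets none.

The stacked regression's error degrees of freedom, $(N-1)p$, are a
bookkeeping convention (the $N \cdot \text{cells}$ stacked observations
are not independent); the construction is exactly equivalent to the
classical univariate RM-ANOVA: for 2-level factors $F$ equals the squared
paired $t$, and for multi-level factors $F$ equals effect MS over
effect-by-subject MS (both are test oracles).

**Epsilon.** $\varepsilon = (\sum \lambda)^2 / (d \sum \lambda^2)$ over
the eigenvalues $\lambda$ of the covariance matrix of the reduced data's
cell columns (divisor $N-1$), with $d$ the number of eigenvalues above the
relative tolerance $\lambda_{max} \cdot 10^{-10}$. $d$ rather than a fixed
$p$ keeps $\varepsilon \in [1/d, 1]$ when the reduced data are rank
deficient. An all-zero reduced matrix (no variance in the contrast space)
reports $\varepsilon = 1$ with a degenerate-data warning.

**Between-subject terms.** Group factors are effect-coded like within
factors, per subject, and the $k-1$ score columns are centered over
subjects. An interaction predictor set is all products of the replicated
within-coding columns with a subject's centered group scores (or centered
covariate value); the regression is otherwise unchanged, with error df
$(N-k)p$ for $k$ groups and $(N-1)p$ for a covariate. Centering is what
keeps a within-subject effect that everyone shares from masquerading as a
group interaction when group sizes or means differ; with centering such a
shared effect can only enlarge the error term, making the interaction
test conservative in its presence, never anti-conservative (the tests
verify both directions). Because only the interaction products enter the
model, pure within-subject results are bit-identical whether or not any
between-subject variable is supplied. Group main effects are reported as
a one-way ANOVA on subject means. Between-by-between interactions
(group × group, group × covariate) are not defined by this formulation
and are not implemented.

**Randomization tests.** The within-subject null distribution multiplies
each subject's reduced row by ±1 (independent fair coin per subject and
iteration) — an isometry per row that preserves the between-column
dependency structure — and recomputes F; the covariate null permutes the
covariate across subjects. $p$ is the plain proportion of null F values
≥ the observed F (ties count), so $p = 0$ is possible at finite
iterations; a `smoothed` option gives $(c+1)/(I+1)$ instead. One seeded
generator per invocation makes runs reproducible. Group-label permutation
is not defined by this formulation and is not implemented.

**Unpacking.** An interaction of order $m$ is decomposed by fixing each
level of its final involved factor (the one with the highest design
index), slicing the data to that level's cells, and re-testing the
$(m-1)$-order effect among the remaining factors, recursively down to
simple main effects; each child equals a direct test on the sliced data.
Pairwise paired t-tests run between all conditions spanned by the
involved factors (other factors marginalized), two-sided, df $N-1$.
Neither follow-up is corrected for multiplicity: they are descriptive
and protected by the significance of the parent interaction, which the
report flags at the configured alpha (default .05).

## Synthetic null data and the false-positive-rate study

`gen_null_data` draws subject-by-cell scores from a standard normal, then
induces condition dependency: floor(cells/2) columns, chosen uniformly
without replacement, are each replaced by
$(1-dep) \cdot \text{column} + dep \cdot \text{mean(other columns)}$,
using the pre-mixing values for all replacements (simultaneous update, so
the result is independent of selection order). $dep = 0$ leaves columns
independent; $dep = 1$ makes each selected column exactly the mean of the
others. Group labels come from $\lfloor k \cdot \text{uniform} \rfloor$
per subject (random, generally unbalanced sizes; a balanced round-robin
option exists for tests), covariates are standard normal. No true effects
exist by construction.

The FPR study sweeps $dep$ over 0, 0.1, …, 1 for a design with 3- and
4-level within-subject factors, two 3-level between-subject factors and
one covariate — 14 effect types per dataset (3 within, 2 group mains,
6 group × within, 3 covariate × within) — and records each effect's
rejection proportion at alpha = .05 and mean p.

What this generator emulates: correlated repeated measures with a
controllable, worst-case-swept degree of sphericity violation, random
group assignment, and an uninformative covariate. What it does not:
non-normal or heavy-tailed noise, missing data, unequal cell variances
across subjects, or true effects (power is exercised separately by
injecting fixed mean shifts, which must yield rejection rates increasing
in effect size and sample size). Passing the FPR sweep therefore shows
calibration under dependency, not robustness to non-normality — that is
what the randomization tests are for.

## Problem sizes and tolerances

* Simulation sample size: 24 subjects (a typical within-subject
  experiment; the effect-wise tests' calibration does not depend on N
  beyond Monte-Carlo noise).
* FPR sweep: 4000 iterations per dependency factor in
  `scripts/acceptance.py`, 2000 in the test suite; the worst-case rate
  over all 154 (dep, effect) pairs is compared against 0.054 plus three
  binomial standard errors at the iteration count used. These sizes put
  the Monte-Carlo standard error of each rate at ~0.003–0.005, small
  enough that the worst-of-154 statistic is informative.
* Permutation validity checks: 300–400 outer replicates × 200–250 inner
  iterations; uniformity via a Kolmogorov–Smirnov statistic with an
  allowance of one inner-iteration quantum for the discreteness of
  permutation p-values.
* Numerical tolerances: projection idempotence and oracle equivalences at
  1e-10; eigenvalue rank tolerance $\lambda_{max} \cdot 10^{-10}$;
  rank-deficient predictor sets solved by pseudoinverse with a warning.
* Missing data: listwise deletion with a warning.

## Design choices that were genuinely open

* **Sign of the worked reduction.** Projecting the centered row
  [-2 4 3 -7 1 1] onto [-1 1 -1 1 -1 1] gives a slope of −2/3 and fitted
  values starting at +2/3. Published accounts of this example sometimes
  print the opposite sign; the projection is implemented as defined and
  tests assert the magnitudes (2/3) and the alternating sign pattern.
* **$d$ in the epsilon denominator** is the count of nonzero eigenvalues
  (not the number of subjects), which keeps the formula's range correct
  and reduces to the familiar $(l-1)$ for a full-rank $l$-level factor.
* **Epsilon for between-interaction tests** comes from the within-reduced
  matrix: per-subject scaling by a group score or covariate does not
  change the sphericity structure of the contrast space.
* **Covariate interaction df** uses $(N-1)p$, mirroring the within test
  it is defined as a scaled version of (no $-k$ adjustment exists for a
  continuous score).
* **Effect order in reports** is mains first, then 2-way, 3-way, …
  blocks, lexicographic within each block, so output is deterministic.
* **Unpacking runs for every interaction**; output is flagged
  "protected"/"unprotected" by the parent's p-value rather than being
  suppressed, since the follow-ups are descriptive either way.

## Known limitations

* Balanced within-subject designs only; no Huynh–Feldt or lower-bound
  corrections; no MANOVA-style multivariate tests.
* The effect-wise between-subject formulation intentionally differs from
  pooled ANCOVA-style joint models and will not reproduce their numbers.
* Monte-Carlo permutation only (no exact enumeration of the $2^N$ sign
  assignments); permutation p-values have resolution 1/iterations.
* The group×within test is conservative in the presence of a large
  shared within-subject effect (see above); its calibration statement is
  exact only under a pure null.
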