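# Methods

## The model

`bridgenet` estimates a pairwise Markov random field over p = 76 variables
of two kinds: 30 ordinal symptom items treated as unordered categoricals
with L = 4 levels, and 46 continuous metabolite measures (modelled Gaussian
on the post-log, covariate-residualised scale). The joint log-density is

    f(x, y) =  Σ_i θ_i[y_i]  +  Σ_j ( α_j x_j / σ_j² − x_j² / 2σ_j² )
             + Σ pairwise terms − log Z,

with pairwise terms c·x_i x_j, ρ[y_i]·x_j and M[y_i, y_j]. Categorical
parameters follow a reference-level convention (entries indexed by level 0
are zero), which makes the nodewise regressions identifiable. Under this
parameterisation a positive Gaussian–Gaussian coupling c contributes
+σ_i²·c·x_j to node i's conditional mean; the implied joint precision
off-diagonal is −c, so positive couplings produce positive marginal and
partial correlations and generator couplings are directly comparable to
recovered edge weights.

### Estimation

Nodewise conditional regressions: OLS for continuous nodes (categorical
neighbours one-hot encoded with the reference level dropped; levels absent
from a sample are dropped from the design with a logged warning) and
maximum-likelihood multinomial logistic regression for categorical nodes.
No sparsity penalty is used by default: cross-group edges are
substantially weaker than within-group ones and are the first casualties
of uniform shrinkage. A ridge `penalty` exists solely to rescue
multinomial separation (detected as perfect in-sample prediction with
runaway coefficients); the Wald covariance for categorical nodes is the
inverse observed information computed at the fitted coefficients.

Aggregation follows the mixed-graphical-model convention: the weight of
edge (i, j) is the mean of the two directions' mean absolute free
coefficients; a sign is attached only when every free entry of both blocks
shares it (always the case for Gaussian–Gaussian edges, where both
directional coefficients equal −Θ̂_ij scaled by a positive factor).

### Edge presence

An unpenalised fit assigns a nonzero coefficient to every pair, so a
presence rule is needed to obtain a sparse graph. The default is a Wald
block test per neighbour at a **family-wise level of α = 0.05 per node**
(Bonferroni over the node's p−1 candidate neighbours), with the two
directional decisions combined by AND. Rationale: with 2850 candidate
edges (1380 cross-group), a per-test α = 0.05 rule would admit on the
order of a hundred spurious cross-group edges — incompatible with the
sparse bridge structure this analysis is designed to isolate — whereas the
per-node correction is the standard neighbourhood-selection choice and
keeps the expected spurious cross-group count well below one. Both the
correction (`correction="none"`) and the combination (`presence_rule="or"`)
are configurable, as is a pure magnitude threshold (`rule="magnitude"`,
`tau`).

### Centrality

Betweenness and closeness use edge length 1/weight on magnitudes (signs
are ignored for path metrics; negative edges are rare and the transform is
the convention of the network-psychometrics visualisation ecosystem).
Closeness is the inverse mean distance restricted to reachable nodes;
disconnected components are logged. The two ratio measures
(betweenness/degree, closeness/degree — indicators of node-*instability*:
high-ratio nodes are posited to perturb the system strongly when changed)
are computed on **raw** measures before min–max scaling, because scaling
first would make the ratios depend on the arbitrary min–max anchors; a
`ratio_on_raw=False` mode computes them on scaled values for sensitivity.
Ties receive dense ranks, so more than three nodes can carry a top-3 flag.

### Stability

Nonparametric bootstrap: B row-resamples with replacement at full n
(default B = 50), the entire estimation re-run per resample, including
metabolite residualisation when a covariate table is supplied, so
adjustment uncertainty propagates. Absent edges enter as strength 0, so
the percentile 2.5/97.5 intervals reflect selection and estimation
variability jointly. Presence fraction has denominator B exactly.
Resamples that fail to converge are retried with an incremented sub-seed
(cap 3) and then flagged. All potential edges are bootstrapped; focus
edges (those incident to a top-3-flagged node) are filtered at report
time, since restricting first would silently condition on the observed
centrality.

### Validation

For each focal (symptom, metabolite) pair, OLS of the metabolite on the
numeric symptom score under seven covariate sets: sex+age only; statins;
antidepressants; BMI; BMI+smoking; BMI+smoking+AD; BMI+smoking+AD+statins.
Metabolites enter on the post-log, *un-residualised* scale with sex, age
and batch always included as regressors — equivalent to the two-stage
residual approach for the base set (Frisch–Waugh) and cleaner for the
larger sets. The metabolite is the dependent variable (the direction
matching metabolite-relevant covariates such as statins and BMI); the
symptom enters as a single 0–3 slope. A second wave re-runs the ladder
with same-wave covariates; consistency is the fraction of fits significant
in both waves with agreeing signs.

## The synthetic generator

The generator is first-class: it draws from the MRF above by Gibbs
sampling so every downstream stage has ground truth.

* **Sampler.** Many short independent chains run in parallel (vectorised
  across chains; categorical updates by Gumbel-max over conditional level
  scores, Gaussian updates from the exact conditional). `burn_in`
  (default 500 sweeps) is discarded per chain; draws from the same chain
  are `thin` sweeps apart (default 2). Graphs of this size mix fast; the
  all-Gaussian submodel is checked against its analytic covariance in the
  tests. Models are validated on construction (positive variances,
  reference-level zeros, positive-definite continuous precision).
* **Default scenario** mirrors the study shape: 30 four-level items (13
  somatic, 16 mood/cognition, one ungrouped), 46 metabolites in 11
  subclasses, n = 2500 per wave, two independent waves. Within-group
  dependence is banded (chain + second-neighbour couplings; level-product
  blocks for item pairs) and far stronger than cross-group dependence,
  which consists of five planted bridges with slope 0.35 per level —
  chosen once as a "large, clearly detectable" effect at n = 2500.
  Item thresholds are skewed so level frequencies are realistic rather
  than uniform. Metabolites are emitted on the concentration scale via
  expm1 so the cleaning pipeline's ln(1+x) applies exactly.
* **Covariates.** Sex/batch/smoking/AD/statins Bernoulli, age and BMI
  Gaussian with adult-outpatient-cohort-like moments. Binary covariates
  act through their raw indicator, continuous ones standardised. Effects
  on categorical targets shift a uniform-dequantised latent copy of the
  level and re-floor it — a concrete realisation of "additive effect on
  the latent score with re-thresholding" that is an exact identity at
  zero effect. The default scenario gives 13 metabolites a batch shift
  (+0.3), a BMI confounder touching one symptom and one metabolite, and
  small lifestyle/medication effects.
* **Missingness** is MCAR per column; default rates keep every metabolite
  below the 2.5% column threshold so filtering costs a few percent of rows
  only (mirroring a complete-case loss of ~3%).

What the generator does **not** emulate: realistic NMR spectra or assay
noise, missing-not-at-random mechanisms, longitudinal correlation between
waves (wave 2 is an independent draw), or the empirical joint distribution
of real symptom items beyond marginal skew. Passing tests therefore show
that the pipeline recovers known conditional-dependence structure under
realistic shapes and confounding — not that any specific real-data edge
list would be reproduced.

## Numerical choices and degenerate inputs

* Cleaning rules use strict inequalities (> 5 s.d., > 2.5%); outlier
  mean/s.d. are computed once, on the post-log scale, before masking.
  Constant columns mask nothing (s.d. 0). The ln(1+x) transform is the
  one non-idempotent stage of the pipeline; the filter and the
  residualisation projection are idempotent and tested as such.
* Wald tests: F for OLS blocks, χ² from the observed information for
  multinomial blocks. Rank-deficient designs raise a collinearity error
  naming the node rather than silently pseudo-inverting.
* Min–max scaling of a constant measure returns 0.5 with a warning;
  zero-degree nodes get ratio 0 with a logged note; zero-weight edges are
  structurally absent (1/weight would otherwise be undefined).
* Seeds: every stochastic stage takes one integer; internal fan-out uses
  `numpy.random.SeedSequence`, so a single master seed reproduces the
  demo dataset, the bootstrap and the pipeline bit-for-bit.

## Problem sizes used in the checks

The automated checks run the full study shape where it matters and scale
down elsewhere: planted-structure recovery uses the complete 76-node
scenario at n = 2500 with a B = 20 bootstrap; the null-calibration runs
use a reduced zero-cross-coupling scenario (5 items, 7 metabolites,
n = 2500, 40 replicates) so the per-edge flag rate is averaged over many
null edges; oracle comparisons use p = 6 (Gaussian equivalence, n = 5000)
and ≤ 7 nodes (brute-force path enumeration, 50 graphs).

## Known limitations

* Pairwise interactions only; no k-way terms, no time-varying networks,
  no regularisation-path selection (EBIC/CV is deliberately not offered).
* The multinomial Wald covariance under ridge rescue is the unpenalised
  information formula evaluated at the penalised optimum — adequate for a
  rescue path, not exact.
* Specialised bridge-centrality statistics (e.g. bridge betweenness) are
  out of scope; the five classical measures plus the two ratios are
  implemented.
* Case-dropping stability coefficients and formal cross-wave network
  comparison tests are not implemented (the latter is undefined for mixed
  categorical/Gaussian data).
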