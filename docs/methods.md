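# Methods

This note documents the statistical models implemented in `phylocausal`,
the choices made where the methodology left the design open, and what the
synthetic-data generator does and does not emulate.

## The problem

Cross-linguistic (and more generally cross-species) samples are not
independent observations: related languages inherit traits from common
ancestors, and neighboring languages exchange them. The package implements
a three-stage analysis of binary traits on a fixed rooted phylogeny that
addresses this non-independence explicitly:

1. **Phylogenetic signal** — does each trait track the tree at all?
2. **Phylogenetic path analysis** — which causal structure among the traits
   is best supported, once the tree is controlled for?
3. **Spatiophylogenetic mixed models** — do the conclusions survive when
   residual variation may be phylogenetic, spatial, or both?

The shipped trait derivation targets three grammatical features of
argument marking (`case`, `verb_final`, `flexible` word order) built from
five raw feature codes (GB070, GB131–GB133, GB136), but every stage accepts
arbitrary binary trait matrices.

## Trait derivation and alignment

`case` is the raw presence code for morphological case on non-pronominal
core arguments (GB070). `verb_final` is 1 only when verb-final order is
coded present *and* both verb-initial and verb-medial order are coded
absent; it is 0 whenever a non-final order is present; any other pattern is
missing. A taxon coded verb-final *and* verb-initial/medial simultaneously
is coded 0 by default ("not exclusively verb-final"), with an `na` policy
available. `flexible` is the negation of the fixed-order code (GB136).

Missing data are handled by listwise deletion over the three derived traits
before any analysis, giving a single shared sample for every stage.
Completeness is applied first, then the intersection with the tree's tips.
Trees are rescaled to unit height before building the Brownian correlation
matrix `rho[i,j] = depth(mrca(i,j)) / depth`, so regression-scale
parameters are comparable across trees. Polytomies are accepted on input
and resolved left-to-right into zero-length binary branches where an
algorithm needs sister pairs.

## Phylogenetic signal: the D statistic

For a binary trait, internal-node values are estimated in one post-order
pass of branch-length-weighted child averaging (weights 1/length, with a
relative floor of 1e-9 of tree height so zero-length branches from
polytomy resolution dominate their sister without infinities). The observed
statistic is the sum over internal nodes of |left child − right child|.
Two simulated references calibrate it:

* *random*: tip values permuted across tips (no signal; D ≈ 1),
* *Brownian threshold*: a Brownian liability simulated along the branches
  and thresholded at the empirical quantile that reproduces the observed
  count of 1s exactly (strong signal; D ≈ 0).

`D = (d_obs − mean_brownian) / (mean_random − mean_brownian)`. Both null
sizes default to 1000 and a seed is required; there is no global random
state. Tail probabilities are one-sided proportions: `p_random` is the
fraction of permuted sums ≤ the observed sum (departure from the random
pole), `p_brownian` the fraction of Brownian sums ≥ the observed sum
(departure from the Brownian pole). Because both references are simulated
with the same node-averaging machinery, the statistic is self-calibrating:
on simulated 200–500-tip trees the mean D of shuffled traits sits near 1
and of threshold-Brownian traits near 0 (the acceptance suite checks the
[0.85, 1.15] and [−0.15, 0.15] bands).

A note on exact monotonicity: concentrating a clade on its majority value
almost always lowers the sister-difference sum, but not provably in every
single case — flipping a clade's mean to an extreme can move its root
value *away* from its sister's. Brute-force search found ~1% of clade
operations increasing the sum slightly; the test suite asserts the
statistical form of the property.

## Causal graphs and their testable content

Causal models are DAGs over the trait names. The testable content of a DAG
is its d-separation basis set: one conditional-independence claim per
non-adjacent vertex pair, conditioning on the union of both vertices'
parents. The regression response within a claim is the member of the pair
that is not a causal ancestor of the other (ties broken lexicographically),
so claims are tested in the causally downstream direction. The claim count
is always C(|V|,2) − |E|, and the basis set is validated against an
independent path-blocking d-separation oracle over all DAGs with up to
four vertices.

The built-in comparison set holds twelve models over {case, verb_final,
flexible}: four single-edge models (verb_final→case from the processing and
noisy-channel hypotheses; case→flexible from licensing theory; and their
two reversals) and eight two-edge models. Three two-edge topologies are
fixed by the study being reproduced — the fork at case (b), the chain
verb_final→case→flexible (c), and the chain flexible→case→verb_final (d).
The original figure does not identify the remaining five topologies, so the
package completes the set with the other four chains plus the collider into
case: every two-edge structure in which one feature mediates or jointly
receives the word-order/case influences. Letters other than b/c/d and i–l
are package-assigned; interpret results by edge set, not letter. Markov
equivalence (same skeleton and colliders) is computed and reported, because
equivalent models — b, c and d among them — are observationally
indistinguishable and their relative ranking carries no structural
information. The parameter count entering the information criterion is
`q = |V| + |E|`, which reproduces the published per-model counts for all
thirteen rows (two-edge 5, one-edge 4, null 3).

## Regression engines

**Gaussian PGLS** solves `beta = (X' C^-1 X)^-1 X' C^-1 y` through a
Cholesky whitening of the correlation matrix (diagonal jitter escalated
from 1e-10 to 1e-6 before failing), with t-based p-values on n − p degrees
of freedom. It is exactly permutation-equivariant and reduces to OLS at
the identity correlation.

**Phylogenetic logistic regression** is a quasi-likelihood (PQL-style)
estimator: iteratively reweighted GLS of the logistic working response
under a working correlation `R(lambda) = lambda * rho + (1 − lambda) * I`,
with the scalar signal parameter `lambda` in [0, 0.995] profiled on a
restricted-likelihood criterion of the working response and then frozen so
the iteration has a well-defined fixed point. The attenuation form was
chosen over an exponential-distance decay after calibration experiments:
thresholding a tree-correlated liability shrinks pairwise correlations
roughly proportionally, and the proportional family keeps null p-values
uniform (≈5% rejection at the 5% level) where the exponential family was
badly anticonservative (≈24%). A quasi-likelihood dispersion is estimated
from the whitened working residuals and p-values use t with n − p degrees
of freedom. At `lambda = 0` the estimator is exactly ordinary logistic
regression, which provides the oracle test against standard MLE.

Separation: a weak Gaussian ridge (prior sd 50 per coefficient, perturbing
regular fits by < 1e-4) guarantees finite estimates; if the iteration finds
no interior fixed point at that level — which happens when the data are
(near-)separated — the shrinkage escalates (sd 10, 5, 2.5) until one
exists. Fits report a converged flag; non-convergence is an error in the
pipeline.

**Claim tests** use a score-type one-step procedure rather than a Wald test
on the fully iterated full model: the model *without* the tested predictor
is fitted by full IRLS, then a single GLS step is taken with the predictor
added, holding the restricted weights and signal parameter fixed. When a
claim is strongly violated the full model is separated and the PQL
iteration can cycle at astronomical values; the one-step statistic is
always finite, asymptotically equivalent to the score test under the null,
and empirically calibrated (KS uniformity p = 0.33 across 150 null
simulations at n = 200, including conditioning variables). Path
*coefficients* (each child regressed on its parents) still come from the
fully iterated fit, whose designs are not separated in practice.

Standardized path coefficients multiply each link-scale coefficient (and
its Wald 95% bounds) by the sample standard deviation (ddof = 1) of its
predictor; binary predictors use their 0/1 standard deviation.

## Path analysis scoring and averaging

Claim p-values are floored at 1e-300, combined into Fisher's
`C = −2 Σ ln p` (chi-square with 2k df under the model), and penalized as
`CICc = C + 2 q n / (n − 1 − q)`. Models are ranked by CICc with ties
broken by fewer parameters then model id; relative likelihoods are
`exp(−ΔCICc/2)` and weights normalize them over *all* fitted models
including the null, which reproduces the published weight column within
rounding. Identical claims shared between models are tested once (cached).

The top set is every model with ΔCICc ≤ 2 whose C-statistic p-value is
≥ 0.05 — a significant C means the model's own independence claims are
rejected. Conditional model averaging renormalizes the CICc weights within
the subset of top models containing each path; paths unique to one model
pass through unchanged. Interval bounds are averaged with the same weights
as the estimates — the averaging of uncertainty intervals is a documented
assumption, not a derived confidence procedure. Full-set averaging (absent
paths counted as zero) is available behind a flag.

## Spatiophylogenetic logistic mixed models

The Bayesian model is `logit Pr(y_i = 1) = x_i' beta + u_i + v_i` with
`u ~ N(0, sigma_p^2 S_phylo)` and `v ~ N(0, sigma_s^2 S_spatial)`, each
correlation matrix normalized to unit diagonal so the two scales are
comparable. Spatial correlation is Matérn with range `phi = 1.25` and
smoothness `kappa = 1` over great-circle (haversine, R = 6371 km)
distances expressed in units of 200 km — a scaling chosen so correlation
is substantial within a few hundred kilometers and falls below 0.05 near
1000 km; the unit is a configuration knob. Priors are weakly informative:
Normal(0, 2.5) on fixed effects, half-Student-t(3, 0, 2.5) on the scales;
all configurable.

Sampling is by Pólya-Gamma data augmentation: given `omega_i ~ PG(1,
eta_i)` the likelihood is Gaussian in the linear predictor, so fixed
effects and random-effect vectors have exact multivariate-normal Gibbs
updates. PG variables are drawn from the convolution-of-gammas series
truncated at 100 terms with a deterministic mean correction for the tail.
Random-effect vectors are updated in whitened coordinates (`u = L a`,
`a ~ N(0, sigma^2 I)` with `L` the correlation Cholesky), which keeps the
conditional precision well-conditioned even for nearly singular tree
correlations. Each scale is updated twice per sweep by univariate slice
sampling — once in the centered and once in the whitened (ancillary)
parametrization (an interweaving scheme) — because the centered update
alone mixes very slowly; interweaving brought split-R-hat from ~1.3 to
≤1.06 at 2×500 draws in the recovery experiments. Defaults are 4 chains
of 1000 warmup + 1000 draws with a convergence gate at split-R-hat 1.01
(arviz); a gated fit raises with its diagnostics attached.

K-fold comparison (default K = 10, simple random partition from the seed)
refits each random-effect structure per fold and scores held-out
observations by expected log predictive density; held-out random effects
are drawn from their conditional Gaussian given the training effects, draw
by draw. Pairs whose |elpd difference| < 2 SE are flagged as equivalent.
Fold fits use short chains and skip the convergence gate. Refits of the
supported path models express each directed path as a logistic GLMM of the
effect on its cause(s) with a phylogenetic random effect only (the same
structure for every response, for comparability), reporting posterior means,
95% credible intervals, and whether each interval includes zero.

## Synthetic data

Trees are Yule (pure birth) with the given tip count, scaled to unit
height. Traits are generated by thresholding liabilities in topological
order of a chosen causal DAG: each trait's liability is an independent
Brownian motion on the tree plus `beta × (centered parent indicator)` per
incoming edge, thresholded at the empirical quantile matching its target
prevalence exactly. With an edgeless DAG this is exactly the signal
module's threshold-Brownian simulator (shared code path, shared per-trait
seed stream). Defaults mirror the study sample: prevalences 0.33 (case),
0.37 (verb-final), 0.38 (flexible) — the observed marginal frequencies —
and structural effects of 1.5 on the liability scale, strong but not
deterministic coupling. Coordinates come from Gaussian clusters around
uniform sphere points; spatially structured traits threshold a Matérn
Gaussian field over their haversine distances. A Grambank-style long-table
emitter inverts the feature derivation exactly (round-trip identity),
choosing verb-initial vs verb-medial by seed for non-verb-final taxa.

What the generator does *not* emulate: language contact and borrowing,
areal diffusion along the tree, tree-shape effects beyond Yule, missing
data patterns, or dated calibrations. Passing recovery tests therefore
demonstrate internal consistency of the estimators under the threshold
model, not robustness to the full messiness of observational linguistic
data.

Because the generating model-c topology is Markov-equivalent to models b
and d, no observational method can systematically distinguish the three;
structure-recovery experiments therefore score a run as successful when
the CICc-best model lies in the generating model's Markov equivalence
class, and additionally track how often the exact letter wins.

## Problem sizes used by the test suite

The suite favors sizes that exercise every code path at meaningful power:
D calibration uses 20 replicates per pole on 250-tip trees with
1000-draw nulls; structure recovery uses 25 seeded runs at 500 tips;
claim-test null uniformity uses 150 independent simulations at 250 tips;
GLMM scale recovery uses 20 runs at 150 tips with 2×500-draw chains, and
the cross-validation discrimination check uses 120-tip datasets. The
acceptance script's single reported quantity is deterministic desk
arithmetic recomputed through the scoring module.

## Known limitations

* The logistic engine is quasi-likelihood, not exact maximum likelihood;
  its signal parameter is a working-correlation knob, not a consistently
  estimated evolutionary parameter.
* Conditional-averaging interval bounds are weighted means of member
  intervals, which has no strict coverage guarantee.
* The PG Gibbs sampler updates scales by slice sampling and can need more
  draws than gradient-based samplers for very weakly identified scale
  posteriors (small n, intercept-only designs).
* Tests involving a single fixed tree per replicate ignore phylogenetic
  uncertainty; the package operates on one tree by design.
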