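# Methods

## Scope and data model

The package analyses sociality in a fission–fusion animal society from
three inputs: a long-format sighting table (one row per individual per
survey, with group id, date, coordinates and water depth), an individual
attribute table (mtDNA haplotype, sponger flag, mean depth, sighting
span), and a pairwise biparental relatedness matrix. Associations follow
the gambit of the group: all members of a surveyed group are taken to be
associating. Analyses run at two levels — dyadic (bond strength) and
community (network subdivision).

## Association index and "not applicable" masking

For a dyad (a, b) the Simple Ratio Index is x / n_either, where x counts
surveys in which the two shared a group and n_either counts distinct
surveys in which either was seen (an individual sighted twice in one
survey counts once; this deduplication is a design choice, the
convention is not universal). Dyads that could not physically associate
carry no index. Two masks implement this:

* **demographic** — the individuals' first–last sighting intervals do
  not overlap (boundary inclusive: one shared day keeps the dyad).
  "Demographic overlap" is operationalised this way because sighting
  spans are the only temporal information in the inputs.
* **geographic** — kernel home-range overlap below 25%, strict
  inequality, so exactly 25% is kept.

Masked dyads enter downstream graphs as absent edges: modularity has no
native missing-data concept and a masked pair contributes no
co-occurrence weight. Missing genetic data is *not* a mask — dyads
without genotypes stay in the network and are dropped only from the
dyadic model (complete-case, with the dropped count logged).

## Home ranges

Utilisation distributions are isotropic Gaussian KDEs on a regular grid
padded three bandwidths beyond the data extent, cell size bandwidth/4
(capped at 512 cells per axis). The default bandwidth is the reference
(href) rule sigma * n^(-1/6); it is configurable because the original
field analysis does not state its choice. The 95% home range is the
smallest set of cells holding 95% of the mass. Overlap is the volume of
intersection VI = sum min(f_a, f_b) * cell area, computed by default
after truncating each UD to its own 95% isopleth and renormalising —
the overlap "of 95% home ranges" — with `restrict_95=False` exposing
the full-UD variant since conventions differ. UDs with fewer than five
sightings are undefined and their dyads masked. Mismatched grids are
bilinearly resampled to a common grid; disjoint extents short-circuit
to VI = 0.

## Dyadic model

Bond strength is modelled as a zero-inflated binomial GLMM on the dyad
counts (y = surveys together, n = surveys either):

    y_d ~ pi * delta_0 + (1 - pi) * Binomial(n_d, p_d)
    logit(p_d) = beta0 + beta1 r_d + beta2 h_d + beta3 NN_d + beta4 SS_d
                 + beta5 dd_d + u_i + u_j

with r = relatedness in [0, 1], h = haplotype identity, foraging
identity as two dummies against the mixed-pair reference (so all three
pairwise contrasts are recoverable), dd = absolute mean-depth difference
in metres, and a multi-membership random intercept summing both members'
effects. Priors are weakly regularising: Normal(0, 10) for the fixed and
zero-inflation intercepts, Normal(0, 5) for slopes, half-Cauchy(0, 2)
for sigma_u. Continuous covariates enter on their raw scales (so odds
ratios are per unit relatedness and per metre); `standardize=True` is
available because per-unit scaling conventions vary between studies.

**Sampler.** Parameters are estimated by an adaptive
Metropolis-within-Gibbs sampler (numba-compiled), 4 chains x 4000
iterations with the first half as warmup. The random effects use the
non-centred parameterisation u = sigma_u * z, which removes the funnel
pathology that trapped centred single-site updates at sigma_u ~ 0. Each
iteration combines per-coordinate and adaptive-covariance (Haario) block
updates of beta, two single-site sweeps over z (each touching only that
individual's dyads, with per-dyad log-likelihoods cached), a
likelihood-invariant move trading the intercept against mean(z), a
random-walk update of log sigma_u through the likelihood, and a
random-walk update of logit pi. Proposal scales adapt during warmup by
Robbins–Monro toward acceptance 0.44 (scalar) and 0.25 (block).
HMC-specific settings (target acceptance 0.99, maximum tree depth 15)
are accepted in the model spec for interface compatibility and are
no-ops for this backend. Convergence requires rank-normalised R-hat
<= 1.01 for *every* parameter (fixed effects, all u, sigma_u, pi);
failing fits are retried with doubled chain length up to twice before
returning `converged=False` with a logged diagnostic.

**Derived quantities.** Odds ratios are exp(beta) posterior summaries
with equal-tailed 95% intervals. Bayesian R² per draw is
Var(yhat) / (Var(yhat) + Var_res), with yhat = (1 - pi) p the model mean
proportion per dyad and Var_res the mean ZIB sampling variance of y/n.
Foraging contrasts (NN–MIX, SS–MIX, NN–SS) are posterior odds-ratio
distributions with intervals widened to level 1 - 0.05/3 for the
three-contrast family, the Bayesian analogue of a Tukey correction.
VIFs come from regressing each covariate column on the others.

## Community detection

Communities maximise weighted Newman modularity

    Q = (1/2m) sum_ij (w_ij - k_i k_j / 2m) delta(c_i, c_j)

via igraph's multilevel (Louvain) heuristic. Because the heuristic is
vertex-order dependent, detection runs 100 restarts over random vertex
orders and keeps the partition with the highest independently
recomputed Q (ties: fewer communities, then lexicographic labels).
Q > 0.3 is reported as a meaningful division. *Limitation:* on dense
near-null graphs (Q around 0.1) greedy modularity heuristics — Louvain
and Leiden alike — can terminate below the exhaustive optimum
regardless of restarts; the exhaustive-agreement test therefore uses
modular graph families, the regime where the 0.3 threshold declares
structure interpretable at all.

## Permutation tests

Four null procedures probe community assortment, each with 10,000
iterations by default:

* **relatedness** — individuals' community labels are shuffled
  (community sizes preserved; individual labels, not dyadic values, are
  exchangeable) and per-community mean dyadic relatedness recomputed;
* **haplotype / foraging identity** — each dyad's sharing indicator is
  redrawn iid Bernoulli(p-hat) and within/between-community means
  recomputed. Default p-hat is the pooled observed proportion of
  sharing dyads; `p_hat_mode="freq"` uses expected sharing from class
  frequencies (sum of squared frequencies);
* **depth** — individual mean depths are reassigned to communities of
  the observed sizes and per-community SDs recomputed; a smaller
  observed than permuted SD indicates habitat homogeneity.

p-values follow the doubled-tail rule: twice the share of permuted
values at least as extreme as the observed one, capped at 1; a zero
count is reported as "< 2/n_perm". The literal rule is upper-tail only;
applied to the depth SD statistic (whose alternative is *smaller*
values) it would always exceed 1, so the default `direction="auto"`
picks the tail by the sign of observed minus the null median, and
`direction="upper"` reproduces the literal rule. Communities of size
one have undefined statistics and are reported as missing.

**Calibration.** The label-shuffle tests are exact permutation tests.
The binomial randomisations carry a finite-pool effect: the observed
within-mean is an average over a subset of the dyad pool whose pooled
mean centres the null, giving the observed statistic variance of
roughly (1 - f) times the null's, f being the within-community dyad
fraction. At f around 0.15 (six communities of ~12) the realised type-I
error is about 0.025 at alpha = 0.05 — conservative, never
anticonservative when class frequencies are balanced; with skewed
frequencies dyadic sharing indicators become positively correlated
(sum f^3 > (sum f^2)^2) and push the other way. The calibration suite
verifies the nominal level in a small-f design (twelve communities of
five).

## Closest associates

Each individual's closest associate is the unmasked partner with the
highest SRI; ties retain all tied partners, contributing fractionally
to class proportions. Per class, k_same successes out of n focal
individuals are tested against p0 = the class's share among potential
partners (the focal excluded — an individual cannot be its own
associate) with a one-sided upper exact binomial test (the homophily
direction), Bonferroni-corrected for the two classes.

## Synthetic societies

The generator emulates the study conditions: 75 adult females (dependent
calves are not generated), 12 matrilines carrying distinct mtDNA
haplotypes inherited maternally, six communities ordered along a 0–17 m
depth gradient with home centres spaced 1000 m (comparable to the
~780 m home-range spread, so neighbouring communities overlap and only
distant ones fall under the 25% mask), pedigree-derived biparental
relatedness (females mate with a founder-male pool, producing full and
half sibs), and vertical transmission of sponging (daughter of a sponger
with probability 0.85, innovation at a low rate that is 25 times higher
in deep than shallow habitat). Surveys (150 by default) detect each
available female with probability 0.4 and assemble groups sequentially:
a random seed opens a group and each remaining candidate joins with
probability sigmoid(theta0 + mean homophily kernel to current members),
where theta0 targets a mean group size of 4 and the kernel carries
log-odds ln 4.25 per unit relatedness, ln 2.83 for shared haplotype,
ln 2.38 for shared foraging class and ln 0.64 per metre of depth
difference — the dyadic effect sizes estimated for the western Shark
Bay females, so the defaults *are* the study conditions. Per-sighting
depth is home depth plus 1 m Gaussian jitter; coordinates are home
centre plus 500 m jitter.

What the generator does **not** emulate: structural never-associate
dyads (all zeros arise binomially, so the fitted zero-inflation
probability is honestly near zero on synthetic data, unlike field data
where it was substantial); observation error in individual identity;
seasonal or long-term demographic turnover beyond randomised sighting
spans; marker-level genotypes (relatedness enters as the pedigree
expectation); and male individuals. Recovered odds ratios are
attenuated relative to the kernel log-odds because group formation
filters the kernel through seeds and group composition — tests
therefore check sign recovery and coverage, not point equality.
Passing tests show the chain recovers planted structure from raw
sightings at field-realistic sizes; they do not certify the magnitude
calibration of any single field estimate.

## Numerical choices and test problem sizes

ZIB log-probabilities use softplus/xlogy forms stable at p in {0, 1}
and pi in {0, 1}; the pmf sums to 1 within 1e-10 over the tested grid.
UD densities are renormalised on their grids (tolerance 1e-6); VI is
clipped to [0, 1]. log sigma_u is bounded in [-12, 8] to keep sigma^2
away from floating-point underflow; the bound is never approached by a
converged fit. Louvain label arrays are canonicalised by first
appearance so partitions compare deterministically; igraph's global RNG
is seeded locally and restored. The test suite runs reduced problem
sizes chosen for CI practicality: sign-recovery replicates use 2 chains
x 1200 iterations (sign posterior mass is insensitive to chain length
at 75 females / 150 surveys), permutation calibration uses 400–500
iterations per replicate across 1000 replicates, and the exhaustive
modularity oracle enumerates all set partitions up to 9 nodes. The
acceptance script runs the full 4 x 4000 configuration.

## Known limitations

* The multilevel heuristic guarantees no global modularity optimum;
  restarts mitigate but cannot remove this (see above).
* The binomial-randomisation nulls are mildly conservative at large
  within-community dyad fractions (see Calibration).
* Closest-associate binomial tests round fractional tie contributions
  to the nearest count; with many ties the test is approximate.
* Home-range estimation assumes projected metre coordinates and a
  single isotropic bandwidth per individual; no coastline clipping.
* The dyadic model treats dyads as conditionally independent given the
  multi-membership intercepts; higher-order dependence (triadic
  closure) is not modelled.
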