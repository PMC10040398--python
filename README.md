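# finsoc

Association networks, dyadic bond-strength models and community analysis
for fission–fusion animal societies — built around the study design used
for female Indo-Pacific bottlenose dolphins in western Shark Bay:
boat-survey sighting records, the gambit of the group, and individual
attributes (biparental relatedness, mtDNA haplotype, tool-use foraging
class, water depth as a habitat proxy).

## What it computes

Starting from a long-format sighting table (one row per individual per
survey), an attribute table and a pairwise relatedness matrix, the
pipeline:

1. **Inclusion filter** — keeps females seen ≥ 10 times in association
   (or ≥ 10 times regardless, `mode="any"`).
2. **Simple Ratio Index network** — SRI(a,b) = x / n_either, the number
   of surveys a and b were grouped together over the number of surveys
   in which either was seen. Dyads that could never associate are
   masked "not applicable": non-overlapping sighting spans
   (demographic) or kernel home ranges overlapping < 25% by volume of
   intersection (geographic).
3. **Dyadic model** — a Bayesian zero-inflated binomial GLMM of
   x | n_either per dyad:

       y_d ~ pi * delta_0 + (1 - pi) * Binomial(n_d, p_d)
       logit(p_d) = beta' x_d + u_i + u_j,   u_k ~ Normal(0, sigma_u)

   with covariates relatedness, haplotype identity, foraging identity
   (both-non-spongers / both-spongers / mixed) and depth difference,
   and a multi-membership random intercept for both members. Priors:
   Normal(0, 10) intercepts, Normal(0, 5) slopes, half-Cauchy(0, 2) on
   sigma_u. Reports odds ratios with 95% credible intervals, Tukey-style
   foraging contrasts, Bayesian R², zero-inflation, R-hat/ESS and VIFs.
4. **Community detection** — best-of-restarts multilevel (Louvain)
   maximisation of weighted Newman modularity Q; Q > 0.3 flags a
   meaningful division.
5. **Permutation tests** — per-community mean relatedness and depth SD
   against size-preserving label shuffles; within/between-community
   haplotype and foraging identity against binomial randomisations;
   doubled-tail p-values (10,000 iterations).
6. **Closest associates** — per-individual top associate and exact
   Bonferroni-corrected binomial tests of same-strategy preference.

A seeded synthetic-society generator (`finsoc.simulate`) produces
populations with matrilineal haplotypes, pedigree relatedness,
vertically transmitted sponging concentrated in deep habitat, and a
grouped survey process with known homophily effects, so the whole chain
is testable end to end.

## Worked example

```bash
python analysis/01_simulate_society.py --seed 1   # data under results/data/
python analysis/02_association_network.py         # SRI + masks
python analysis/03_dyadic_model.py --seed 1       # ZIB GLMM
python analysis/04_communities.py --seed 1        # Louvain + modularity
python analysis/05_permutation_tests.py --seed 1  # community correlates
python analysis/06_closest_associates.py          # foraging homophily
```

With seed 1 the simulated society gives (abridged):

```
75 individuals pass the inclusion filter
2160 of 2775 dyads masked as not applicable; median SRI 0.021, max 0.160
converged: True (max R-hat 1.004)
        effect  odds_ratio  ci_low  ci_high
   relatedness        3.31    2.03     5.04
same_haplotype        1.78    1.50     2.09
   foraging_NN        2.15    1.63     2.84
    depth_diff        0.73    0.70     0.77
Bayes R2 0.579 (0.539-0.618); zero-inflation 0.001
6 communities (sizes [22, 20, 18, 13, 1, 1]); Q = 0.606 -> meaningful
sponger: 67% same-strategy closest associates (n=9, expected 11%), p = 0.0002
```

Read: the odds of two females being surveyed together scale up 3.3-fold
per unit relatedness and 1.8-fold for a shared haplotype, and fall to
0.73 per metre of depth difference — the planted kin, matriline and
habitat homophily recovered from raw sightings. The network splits into
six habitat-ordered communities (modularity 0.61), and spongers pick
sponger closest associates far above their 11% availability.

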