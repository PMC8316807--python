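# Methods

`vocalstyle` implements a two-level comparative analysis of how dominance
style — the strictness with which a dominance hierarchy is enforced,
from despotic to tolerant — relates to vocal communication in group-living
primates, together with a synthetic-study generator that provides ground
truth for validating every estimator in the chain.

## Dominance ranks

Ranks come from **modified David's scores** computed on decided aggressive
bouts only (a bout is decided when the victim flees or submits, and the
winner is recorded). For individuals i, j with s_ij wins of i over j out of
n_ij = s_ij + s_ji decided bouts, the dyadic win proportion
P_ij = s_ij / n_ij is shrunk toward 0.5 by the interaction-count
correction

    D_ij = P_ij − (P_ij − 0.5) / (n_ij + 1),     D_ij = 0 when n_ij = 0.

The score is DS_i = w1_i + w2_i − l1_i − l2_i with w1_i = Σ_j D_ij,
w2_i = Σ_j D_ij·w1_j, l1_i = Σ_j D_ji and l2_i = Σ_j D_ji·l1_j, and the
normalized form normDS_i = (DS_i + N(N−1)/2)/N lies in [0, N−1]. Scores
always sum to zero; ordinal ranks break exact normDS ties by identifier
order and flag them. Individuals appearing in fewer than `min_decided`
(default 3) decided bouts are dropped before ranking — with so little
information their position in the hierarchy is arbitrary.

## Dominance-style measures

Four measures, all proportions of events and therefore insensitive to
differences in how observers delimited bouts:

* **aggression symmetry** (directional inconsistency index, DII): the
  proportion of a dyad's bouts in the less frequent direction,
  min(a, b)/(a + b) ∈ [0, 0.5];
* **counteraggression**: percent of bouts in which the victim retaliates;
* **aggression intensity**: percent of bouts with physical contact by the
  aggressor;
* **feeding proximity**: percent of feeding scans with an independent
  neighbour within 1 m (non-feeding scans never count).

At the individual level each aggression measure is computed twice:
**given tolerance** restricts to dyads whose partner ranks strictly below
the focal (normDS comparison), **received tolerance** to partners ranking
strictly above. Dyads with exactly tied normDS are excluded from both
directions — a tie carries no evidence about who tolerates whom. All bouts
in a qualifying dyad count, whoever initiated: the rank restriction is a
dyad-level filter, matching the relationship-level construct. Across
dyads, DII is pooled by default (summed least-frequent counts over summed
totals) rather than averaged per dyad, so a 1-bout dyad cannot carry the
same weight as a 40-bout dyad; `dii_mode="dyad_mean"` switches to the
unweighted average. A measure is reported missing when backed by fewer
than `min_bouts` (default 10) bouts, and feeding proximity when backed by
fewer than `min_scans` (default 10) feeding scans.

The species-level **composite dominance-style index** is built in four
steps: (i) mean of each measure over the individuals of a group
(unrestricted direction — the species characterization uses all dyads),
(ii) mean over the groups of the species, (iii) z-score of each measure
across species using the sample SD, with aggression intensity negated
first so that every z-score increases with tolerance, (iv) the composite
is the mean of the three z-scores. Positive composite = tolerant species.
The z-scoring makes the index invariant to positive affine rescaling of
any raw measure; a species missing any measure is excluded and logged,
and a zero cross-species SD is an error rather than a silent division.

## Vocal rates

A **vocal bout** is all of an individual's vocalizations within 30 s of
one another: consecutive events chain while the gap is ≤ `ibi_seconds`
(single linkage between events, not between bout onsets; a gap of exactly
30 s chains, reading "within 30 s" inclusively). Bouts never chain across
focal sessions, because a bout cannot be asserted to span unobserved
time. The rate is bouts per summed focal hour, and an individual enters
the models only with ≥ 2 h of focal observation (`min_focal_hours`).

## Individual-level models

Three Gaussian mixed models predict y_i = log10(rate_i + offset):

1. *given tolerance*: given-direction DII, counteraggression, intensity,
   plus group size;
2. *received tolerance*: the received-direction triple plus group size;
3. *feeding proximity*: proximity plus group size.

Random intercepts for species and for group nested in species (group
labels are made unique within species, so identical group names across
species never pool). Predictors enter raw, keeping β interpretable as
change in log10 rate per unit of the raw measure. The default `offset` is
0.01 bouts/h so zero-rate individuals stay in the analysis; the CLI's
`--offset-sensitivity` flag refits at 0.001 and 0.1 to show coefficient
stability.

Fitting is by a **conjugate Gibbs sampler**: diffuse normal priors on the
fixed effects (mean 0, variance 1e10), univariate inverse-Wishart priors
on each variance component with V = 1 and ν = 0.002 (inverse-gamma shape
ν/2, scale νV/2). The fixed-effect block, each random-intercept block and
each variance have closed-form full conditionals, so the sampler targets
the exact posterior of this model with no tuning. Chain defaults
13 000 iterations, 3 000 burn-in, thinning 10 (1 000 retained draws);
runs are bit-reproducible given the seed. Summaries are posterior means,
central 95% credible intervals, and pMCMC = twice the smaller tail
proportion of draws relative to zero, floored at one draw so 0 is never
reported. The variance partition divides the variance of the fitted
linear predictor Xβ̂ and the posterior-mean variance components by their
sum; the fixed-effect share uses the sample variance of Xβ̂ across
individuals.

Numerical notes: the β update solves the p×p precision system by
Cholesky; random-intercept updates are vectorized with `bincount`; a
rank-deficient design or a chain retaining fewer than 100 draws is an
error, not a warning.

## Species-level models

Species traits are the composite index, the mean group size across the
species' groups, and log10(count + 1) transforms of the overall
repertoire size and of the hierarchy-related call count (the +1 offset is
configurable; hierarchy-call counts can be 0, and the same transform is
applied to both counts for comparability). Models are **PGLS** with
residual covariance σ²C, where C[i, j] is the root-to-MRCA depth of
species i and j on a time-calibrated ultrametric tree and Pagel's λ
multiplies the off-diagonals. λ is fixed at 1 — with ~20 species there is
no power to estimate phylogenetic signal, so the models deliberately
assume the maximum — and λ = 0 recovers OLS exactly. Estimation is by
Cholesky whitening (β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y), with t-tests on n − p
degrees of freedom; p-values are invariant to scaling C. Five models run:
the two main ones (each repertoire response on composite + group size)
and three follow-ups replacing the composite by one raw species-mean
measure at a time.

A taxon absent from the reference tree can be grafted as a sister lineage
to a named tip at a stated divergence time (e.g. *Papio kindae* sister to
*P. cynocephalus* at 1.99 Myr); the graft inserts a node on the sister's
terminal branch, preserves ultrametricity exactly, and refuses a
divergence older than the terminal branch rather than silently
reattaching deeper.

## Synthetic studies

The generator emulates the statistical structure the estimators assume,
at the scale of a multi-site comparative field study: 16 species, 2–3
groups each, 6–15 individuals per group, with a species-level latent
tolerance τ ~ U(−1, 1) driving every style probability (see the module
docstring for the exact maps: subordinate-initiation 0.05–0.45,
counteraggression 0.05–0.55, contact 0.60 down to 0.10, feeding-neighbour
0.10–0.40). Dyads interact Poisson(8) times; 80% of bouts are decided and
the aggressor wins 90% of those. Individual log10 vocal rates follow the
nested mixed model with β0 = 0.3, β1 = 0.42 on the expected given-DII,
σ_species = 0.25, σ_group = 0.2, σ_ε = 0.15; vocal bouts are placed in
focal sessions (2–10 h per individual) and exploded into 1–4 calls less
than 30 s apart so the segmentation stage does real work. Repertoires are
Poisson: hierarchy calls with mean exp(1.5 − 0.6 τ) (declining in
tolerance), other calls with mean exp(2.2). The phylogeny is a Yule tree
(birth rate 0.2/Myr) conditioned on the species count, extended by the
waiting time to the next unrealized speciation so terminal branches are
positive, and rescaled to 40 Myr height. Everything is reproducible from
one seed, and the ground truth (τ, expected DIIs, random effects, true
rates, repertoire means, the tree) is stored beside each dataset.

What the generator does *not* emulate: rank-distance or sex effects on
aggression, seasonal structure, observer heterogeneity, and — importantly
— within-species variation in tolerance: τ is a species property, so all
true variation in the vocal model's fixed-effect predictor is
between-species. Passing tests therefore demonstrate correctness of the
estimators under the assumed structure, not robustness to the many ways
real field data deviate from it.

## Calibration and known limitations

`coverage_experiment` freezes one default-design study's design matrix
and regenerates the response from the mixed model with known
coefficients; over 100 replicates the 95% credible intervals show nominal
coverage and negligible bias for every coefficient, confirming the
sampler is calibrated when the predictor truly varies as measured.

End to end, the species-level headline (hierarchy-call repertoires shrink
with the composite index) is recovered with the correct negative sign
essentially always: the repertoire effect (−0.6 per unit τ on the log
scale) is large relative to Poisson noise. The individual-level headline
(positive given-symmetry effect on vocal rate) is, by contrast, weakly
identified under the default generator: because the true predictor is
species-constant, the β1 signal spans only ≈ 0.42 × 0.115 ≈ 0.05 on the
log10 scale between species, against species-intercept noise of 0.25 —
even an ideal species-level regression on the true predictor recovers
the positive sign only ~76% of the time at 16 species, and the full
pipeline (which additionally faces measurement noise in the DII and
collinearity among the three style measures) recovers it roughly half
the time. This is a property of the simulated study design, not of the
estimators; detecting such an effect reliably would require either
within-species tolerance variation or many more species. The end-to-end
direction test records this honestly rather than relaxing its threshold.

Problem sizes used throughout the tests (1 000-group oracle sweeps, 100
calibration replicates, 20 end-to-end seeds, 500 PGLS replicates) were
chosen to give stable Monte-Carlo estimates at interactive runtimes.
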