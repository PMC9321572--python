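# Methods

This note documents the models implemented in `barcodediv`, the
assumptions behind them, the synthetic-data generator, and the numerical
choices that were genuinely open.

## Unit delineation

Input: a rooted ultrametric haplotype tree and a pairwise similarity
matrix. Similarity is `1 − mismatches / compared sites`, counted over
alignment columns where both symbols are unambiguous bases; gaps and Ns
are excluded pairwise from numerator and denominator (p-distance
convention on a fixed alignment). A pair sharing no comparable site is
scored similarity 0 with a warning.

The traversal starts at the root; at each node the mean dissimilarity
over all unordered tip pairs below it is compared with `1 − τ`. Strictly
below ⇒ the clade collapses into one unit and the traversal does not
descend further; otherwise the children are visited. A tip reached
without collapse is a singleton unit. Consequences, both tested:
partitions at larger τ refine partitions at smaller τ, and unit counts
are non-decreasing in τ. Ties (mean dissimilarity exactly `1 − τ`) split,
matching a strict reading of "lower than". The mean is unweighted across
haplotypes; weighting by haplotype abundance is a deliberate non-default
because the traversal operates on the haplotype tree, where each tip is
one sequence variant.

The implementation accumulates pairwise-dissimilarity sums bottom-up, so
the full traversal costs O(n²) regardless of tree shape; it is verified
against a brute-force clade-enumeration oracle on hundreds of small random
instances.

In simulations the delineation runs on the *true* grafted genealogy, not
a re-estimated tree. This is intentional: the measured unit deficit is
then attributable to marker slowness and lumping alone, with no
tree-inference error mixed in, and reports say so.

## Sampling completeness

Chao2 from an incidence matrix: with Q1 uniques, Q2 duplicates, R
samples and A = (R−1)/R,

    Ŝ = S_obs + A·Q1²/(2Q2)            (Q2 > 0)
    Ŝ = S_obs + A·Q1(Q1−1)/2           (Q2 = 0, bias-corrected)

with the classical log-normal 95% interval on Ŝ − S_obs. The sampling
fraction is f = S_obs/Ŝ. Chao2 is used here as the richness estimator
behind sampling fractions; robustness sweeps downstream conventionally
assume fractions of 90–50%. Rarefaction subsamples accession records (not
haplotypes) without replacement on a 5% grid, 100 replicates by default;
the implementation draws one permutation per replicate and reads richness
at every grid size along it, which is an independent draw per replicate
and unbiased at each size (checked against the exact hypergeometric
expectation in the tests).

## Birth–death likelihood

Ages t are measured in Myr before present; branch intervals are
half-open (child age, parent age]. The probability that a lineage alive
at age t leaves no *sampled* descendant solves the Riccati equation

    dE/dt = μ(t) − (λ(t)+μ(t))E + λ(t)E²,   E(0) = 1 − f,

integrated from the present into the past. The crown-conditioned
log-likelihood of a tree with n tips, branching ages t_1…t_{n−1} and
crown age T is

    logL = Σ_i log λ(t_i) − Σ_branches [Λ(t_parent) − Λ(t_child)]
           + n log f − 2 log(1 − E(T)),

with Λ′(t) = λ(t) + μ(t) − 2λ(t)E(t). The parameter-free labelling
constant is fixed at zero for every model, so likelihoods are comparable
across models on the same branching times (with constant λ, μ = 0, f = 1
this reduces exactly to the Yule form (n−1)·log λ − λ·total length, which
the test suite checks against an independently coded closed form).

Numerics: when rates are constant, E has the logistic closed form
u = 1 − E, u(t) = r f e^{rt}/(r + λf(e^{rt}−1)), and Λ follows
analytically; when μ = 0 and f = 1, E ≡ 0 and Λ = ∫λ (closed form for
constant and exponential speciation, trapezoid quadrature on a dense grid
for environmental rates). Everything else goes through `solve_ivp`
(adaptive RK45, rtol 1e-8, atol 1e-10) on the coupled [E, Λ] system, with
an explicit error if E leaves [0, 1]. The closed forms agree with the ODE
path to ~1e-10 in the tests.

Speciation families: constant λ₀; time-exponential λ₀e^{αt} (α > 0 ⇒
higher rates in the past ⇒ decline toward the present); environmental
b·e^{a·env(t)} (a > 0 ⇒ speciation increases with the environmental
value). Extinction: zero, constant (free μ), or pinned at user-supplied
values — the usual robustness sweep against arbitrarily high extinction.
A constant environmental curve makes (a, b) jointly non-identifiable and
is rejected with an explicit error.

Fitting is multi-start Nelder–Mead (10 starts by default, first start at
the Yule moment estimate (n−1)/total length with α = a = 0, the rest
jittered), positive parameters on the log scale, convergence tolerance
1e-8 on the objective. AICc uses k free parameters and n = number of
branching times (internal nodes), stated in every `FitResult`;
"supported" means every rival trails by ≥ 2 AICc units.

Environmental curves are least-squares cubic B-splines whose coefficient
count plays the role of the smoother's degrees of freedom (default 33,
the conventional smoothing for Phanerozoic temperature series); outside
the tabulated range the fit is extended linearly with a warning.

Tree slicing cuts at a reference age (400/200 Ma in typical use): one
subtree per lineage crossing the slice, stem discarded, retained for
fitting iff it has more than 50 tips.

The decline statistic is λ̂(0) − λ̂(t) at reference ages 150/100/50 Ma,
evaluated on the fitted parametric rate function (here the
time-exponential fit). This is a deliberate parametric substitute for
lineage-specific Bayesian rate reconstructions, which are outside this
package's scope; negative values mean a decline toward the present.

## Correlates

θπ is the mean over all unordered pairs of member sequences of the
per-site p-distance (comparable sites only), computed on *all* members
including duplicate haplotypes — the estimator is defined on the sample,
so abundant haplotypes weigh in proportion. Units need ≥ 10 sequences by
default (robustness settings: 15, 20); smaller units are excluded with a
warning.

The niche PCA standardizes ten per-unit variables (numbers of continents,
realms, ecosystems, habitats, biomes and climatic zones occupied; number
of plant partners; their phylogenetic diversity; betweenness and
closeness in the plant–fungus network) and decomposes them. Axis signs
are fixed deterministically: PC1 is oriented to correlate positively with
`nb_continent`, other axes so their largest-magnitude loading is
positive.

Regressions offer three modes. Ordinary least squares with a two-sided
t-test; phylogenetic GLS with Brownian covariance `V[i,j] = T − age of
MRCA(i,j)` from the unit tree (this replaces Bayesian phylogenetic mixed
models — noted in the result metadata; on a star phylogeny it equals OLS
exactly, a tested identity); and a latitude jackknife that redraws a
fixed number of occurrence records (default 1,000) from each 20° latitude
band ([−90,−70), …, [70,90]) to debias uneven latitudinal sampling, with
an empirical sign-test p-value over the slope distribution. Empty bands
are skipped with a warning. Rate responses are log-transformed by default
(rates are positive and right-skewed); configurable.

## Synthetic data

The generator reproduces the structure of the empirical system it
emulates. Species trees: constant-rate birth–death simulated forward in
time from two crown lineages (Gillespie; thinning against a rate bound
when rates are age-dependent), conditioned on both crown lineages having
extant descendants so the reconstructed crown age is exactly the nominal
value (default 505 Myr); up to 1,000 attempts before an explicit failure.
Net rates of 0.010 and 0.015 events/lineage/Myr bracket the empirical
unit counts; the pure-birth expectation E[N] = 2e^{rT} ≈ 312 at r = 0.010
is verified by Monte Carlo. The birth–death scenario needs a turnover
value that the study design leaves open; the default is ε = 0.5,
configurable and echoed in every report.

Intraspecific structure: each species tip is replaced by a coalescent
subtree with k ~ Uniform{2..15} individuals. The subtree root age is
uniform on (0, min(pendant branch length, 30 Myr)) — all individuals
coalesce more recently than the species' last speciation event, read as
the pendant branch origin. Within that constraint the genealogy is a
standard exchangeable coalescent topology with exponential internode
times, rescaled so the root depth equals the drawn age; the within-species
process is otherwise unconstrained by the study design, and this is the
simplest neutral choice. A zero-length pendant degenerates to age 0 with
a warning.

Sequences: 520 bp with exactly ⌊0.25·520⌋ = 130 variable columns chosen
uniformly per replicate; variable sites evolve under Jukes–Cantor
(symmetric single-nucleotide process, uniform base frequencies) at 0.001
substitutions/site/Myr; invariable columns are bitwise identical across
sequences. No indels, no gamma rate heterogeneity. The two-sequence
expected p-distance p_var·(3/4)(1 − e^{−(4/3)s·d}) is verified by Monte
Carlo.

Unit metadata: the ten niche variables are linear (hence monotone)
transforms of a shared latent generalism factor plus independent Gaussian
noise, so PC1 of the standardized table aligns with the factor — at zero
noise the table is exactly rank one. Count-like variables therefore live
on a continuous scale; this is deliberate, since the tables exist to
exercise the PCA and regression machinery, not to mimic integer
marginals. Sequence counts are zeta-distributed (long-tailed, spanning
the ≥ 10-sequence filter); latitudes are drawn per occurrence around
unit-specific centres (U(−60, 60), within-unit sd 15°). The ground-truth
latent factor is kept as a column for generate-then-fit tests.

All generators are bit-reproducible under a fixed seed; the experiment
driver derives independent per-replicate, per-stage streams from one root
seed via `numpy.random.SeedSequence`.

### What the generator does *not* emulate

Real barcode data add alignment error, chimeras, primer and abundance
biases, rate variation among variable sites, and — most importantly —
tree-estimation uncertainty, which the pipeline deliberately bypasses by
delineating on the true genealogy. Passing tests therefore demonstrate
the correctness and the intrinsic behaviour of the method (e.g. how much
lumping a slow marker causes *at best*), not its robustness to inference
noise on real data.

## The lumping-bias experiment

Per replicate: simulate the species tree, graft coalescents, evolve the
marker, collapse identical haplotypes, prune the genealogy to haplotype
representatives, delineate units at τ = 0.99, prune to one representative
tip per unit, fit constant and time-exponential birth–death models
(f = 1), and record counts, the percent deficit 100·(1 − units/species),
and decline statistics. Stage failures are caught and recorded per
replicate; aggregation uses medians (robust to the long tail of tree
sizes). Ten replicates at the full study scale (crown age 505 Myr,
r = 0.010) run in well under a minute on one CPU.

Two opposing forces shape the deficit: young sister species with
near-identical sequences are *lumped* (units < species), while species
with deep intraspecific coalescents can be *split*. At the study's
parameter values lumping dominates and the median deficit lands around
10–20%, accompanied by a spurious preference for declining-rate models —
the artefact the experiment exists to quantify. The companion check
simulates trees under a genuinely collapsing speciation rate and verifies
the artefactual decline is markedly weaker than a real one.

## Known limitations

- Extinction is weakly identifiable from reconstructed trees; the pinned-μ
  sweep probes sensitivity but cannot estimate extinction reliably.
- The decline statistic inherits the parametric form of the fitted rate
  function; it measures monotone exponential trends, not rate shifts.
- Chao2 is a lower-bound-style richness estimator; sampling fractions
  derived from it are correspondingly optimistic upper bounds.
- The latitude jackknife resamples within bands with replacement, which
  under-represents within-band heterogeneity when a band holds few
  occurrences (skipped bands are warned about).
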