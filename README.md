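# barcodediv

Barcode-based diversification analysis for clades whose species are known
mostly from a single short marker — the motivating case being arbuscular
mycorrhizal fungi (Glomeromycotina), where essentially all global diversity
knowledge comes from a ~520-bp variable region of the SSU rRNA gene.

The package provides, as a tested and reusable pipeline:

- **Unit delineation** (`barcodediv.delineate`): species-like *evolutionary
  units* (EUs) from a dated haplotype tree, by a root-to-tip traversal that
  collapses a clade into one unit when the mean pairwise sequence
  dissimilarity of its tips falls below `1 − τ` (monophyly + average
  similarity, thresholds typically 97–99%).
- **Sampling completeness** (`barcodediv.diversity`): rarefaction curves of
  accession records, Chao2 incidence-based richness, and the sampling
  fractions `f = S_obs / Ŝ` passed to the diversification likelihoods.
- **Diversification inference** (`barcodediv.bdfit`): maximum-likelihood
  birth–death fits on ultrametric trees with incomplete sampling —
  constant, time-exponential `λ(t) = λ₀ e^{αt}` and environment-driven
  `λ(t) = b e^{a·env(t)}` speciation, with zero, free or pinned extinction;
  AICc model ranking, tree slicing at a reference age, lineage-through-time
  curves, and speciation-rate decline statistics `λ̂(0) − λ̂(t)` at 150, 100
  and 50 Ma.
- **Correlates** (`barcodediv.correlates`): Tajima's θπ per unit, a PCA of
  ten niche-width variables, and regressions of rates or diversity against
  niche scores, latitude (band-balanced jackknife) or spore size
  (Brownian phylogenetic GLS).
- **Simulation machinery** (`barcodediv.synthdata`, `barcodediv.workbench`):
  crown-conditioned birth–death species trees, grafted intraspecific
  coalescents, slowly evolving barcode alignments, and the end-to-end
  *lumping-bias experiment* quantifying how a slow marker merges young
  species and fakes a speciation-rate decline toward the present.

The likelihood follows the standard reconstructed-tree formulation: with
t the age before present and f the sampling fraction, the probability
E(t) that a lineage alive at age t leaves no sampled descendant solves
`dE/dt = μ − (λ+μ)E + λE²` with `E(0) = 1 − f`; each branch contributes the
factor `exp(−∫(λ+μ−2λE)dt)`, each branching a factor `λ(t_i)`, and the crown
condition divides by `(1 − E(T))²`.

## Worked example

Simulate one replicate of the slow-marker study (pure birth, net rate
0.010/lineage/Myr, crown age 505 Myr), delineate EU99 units on the true
haplotype genealogy, and fit time-dependent birth–death models to the
resulting unit tree:

```python
from barcodediv import *
from barcodediv.synthdata import SimulationConfig

cfg = SimulationConfig.from_net_rate(0.010, crown_age=505.0, seed=42)
sp = simulate_species_tree(cfg)
grafted = graft_intraspecific(sp, cfg, seed=43)
aln = simulate_alignment(grafted, cfg, seed=44)
hap, members = collapse_haplotypes(aln)
hap_tree = grafted.prune_to(hap.names)
part = delineate_eus(hap_tree, pairwise_similarity(hap), tau=0.99)
print(f"species: {sp.n_tips}  haplotypes: {hap.n_sequences}  EU99: {part.n_units}")

summary = partition_summary(part, members)
eu_tree = hap_tree.prune_to(summary["representative"].tolist())
fits = fit_bd(eu_tree, models=("constant", "exponential"), f=1.0)
print(aicc_compare(fits).to_string(index=False))
print(decline_statistic(next(f for f in fits if "exponential" in f.model_id)))
```

prints

```
species: 332  haplotypes: 1015  EU99: 261
          model       loglik  k        aicc  delta_aicc  supported
exponential.mu0 -1485.183308  2 2974.413308     0.00000       True
   constant.mu0 -1493.117747  1 2988.250998    13.83769      False
{150.0: -0.00329, 100.0: -0.00204, 50.0: -0.00095}
```

Read: of 332 true species, the 520-bp marker resolves only 1,015 distinct
haplotypes, and EU delineation at the 99% threshold recovers 261 units — a
21% shortfall caused purely by young sister species sharing near-identical
sequences. Fitting the unit tree then *prefers the time-exponential model*
(ΔAICc ≈ 13.8) with a negative rate change toward the present (−0.0033
events/lineage/Myr relative to 150 Ma): the lumping alone manufactures an
apparent speciation slowdown, which is why the magnitude of such declines
must be benchmarked against this artefact before being read as biology.

The same pipeline is packaged as a CLI:

```sh
barcodediv simulate --scenario pb --r 0.010 --crown-age 505 --seed 1 --out sim/
barcodediv delineate --tree sim/grafted_tree.nwk --aln sim/alignment.fasta --tau 0.99 --out eu99.csv
barcodediv fit --tree tree.nwk --models const,exp,env --env temp.csv --f 0.93 --out fits.csv
barcodediv experiment lumping --scenario pb --r 0.010 --reps 10 --seed 42 --out report/
```

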