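# assemblage

Succession and neutral-assembly analysis of host-associated bacterial
communities, built around the developmental cycle of shrimp larvae in
nursery culture. The package is for microbial ecologists who want to ask,
from an OTU table plus sample metadata: *how fast does the community turn
over in time, and how much of its assembly is neutral (drift + dispersal)
rather than selective?*

It implements, as a tested library with a CLI and a set of analysis
drivers:

- **Sloan's neutral community model.** An OTU with relative abundance *p*
  in a source metacommunity is detected in a local community of *N*
  individuals with probability
  `freq(p) = 1 − I_d(N·m·p, N·m·(1−p))`,
  where *I* is the regularized incomplete beta CDF, *d* = 1/N the
  detection limit, and *m* the migration rate — the probability that a
  death is replaced by an immigrant. *m* is fitted by bounded non-linear
  least squares to the observed occupancy–abundance curve, with the
  rearing water as the source (external mode) or the pooled larval
  metacommunity as its own source (self mode).
- **Per-OTU neutrality classification** against a bootstrap 95% band
  (1000 refits combined with binomial occupancy noise): above-prediction
  OTUs are host-favoured or strong dispersers, below-prediction OTUs are
  selected against or dispersal-limited.
- **AIC comparison** with a zero-parameter binomial sampling model
  (`freq = 1 − (1−p)^N`), separating drift + dispersal limitation from
  pure subsampling.
- **Time-decay of similarity** `S = c·T^w` fitted as
  `log10 S = log10 c + w·log10 T` over all larval sample pairs, for
  taxonomic (Bray-Curtis) and phylogenetic (1 − normalized weighted
  UniFrac) similarity.
- **The supporting diversity stack**: rarefaction, richness, Shannon,
  Pielou, Faith's PD, Bray-Curtis, weighted UniFrac, PCoA, ANOSIM.
- **Synthetic-data generators** with known ground truth (lognormal source
  pool, Dirichlet-multinomial stationary neutral process, an explicit
  forward simulator that validates it, injected non-neutral taxa, a
  six-stage nursery study over 350 h).

## Worked example

```python
from assemblage import simulate as sim
from assemblage.neutral import fit_ncm

p = sim.generate_source(S=300, source_sigma=1.5, seed=1)          # water pool
table = sim.simulate_local_communities(p, N=5000, m_true=0.3,
                                       n_local=50, seed=1)        # larvae
fit = fit_ncm(table, table.sample_ids, source="self", seed=1)
print(f"m = {fit.m:.3f}  r2 = {fit.r2:.3f}  {fit.category_counts()}")
```

prints

```
m = 0.386  r2 = 0.957  {'above': 7, 'neutral': 267, 'below': 25}
```

The fitted curve explains 96% of the occupancy–abundance variance and 89%
of OTUs sit inside the 95% band, close to nominal for purely neutral
data. The fitted *m* (0.386) sits above the generating value (0.3): detection in
reads is "≥ 1 read", whose exact probability exceeds the model's
threshold-at-*d* approximation for rare taxa, so least squares compensates
upward — a documented property of the Sloan approximation (about +20% at
m = 0.05, +30% at m = 0.3 at these sizes; see `docs/methods.md`). Treat
*m* as a dispersal index to compare across conditions.

The full study analysis runs as four numbered drivers:

```bash
python analysis/01_simulate_study.py          # writes results/data/
python analysis/02_diversity_ordination.py    # alpha, PCoA, ANOSIM
python analysis/03_time_decay.py              # turnover exponents
python analysis/04_neutral_fits.py            # stage-wise NCM fits
```

`03` reports, for the simulated nursery,

```
taxonomic     turnover: w=-0.2020  r2=0.675  p=0.00e+00  (2277 pairs, 69 excluded)
phylogenetic  turnover: w=-0.0576  r2=0.640  p=0.00e+00  (2277 pairs, 69 excluded)
```

— taxonomic turnover is faster than phylogenetic turnover (the random
tree dilutes compositional change), and `04` recovers the declining
water-to-larvae migration trajectory across the three zoea sub-stages
(fitted external-mode m: 0.464 → 0.272 → 0.056 for generating rates
0.309 → 0.226 → 0.042).

The same steps are available as a single pipeline with one config and one
manifest:

```bash
assemblage --seed 1 simulate --out bundle/
assemblage run --config run.yml
```

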