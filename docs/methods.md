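# Methods

## The problem

During larval nursery of penaeid shrimp, each larva carries a small
bacterial community that is continuously reassembled as the animal molts,
starts feeding, and changes diet. Two questions drive the analysis this
package implements: how fast does the larval community turn over in time,
and how much of its assembly is explained by neutral processes — random
drift plus immigration from a source pool (the rearing water, or the other
larvae) — as opposed to host selection.

## Neutral community model

Each local community (one larva sample) is modelled as a fixed pool of N
individuals. At each death, the replacement is drawn from the source
metacommunity with probability m (the migration rate) and from the local
community otherwise. At stationarity the relative abundance x of a taxon
with source abundance p follows

    x ~ Beta(N m p,  N m (1 - p))

and the probability of observing the taxon at all — its expected
*occurrence frequency* across local samples — is the tail mass above a
detection limit d:

    freq(p) = 1 - I_d(N m p, N m (1 - p))

with I the regularized incomplete beta CDF. Given the observed occurrence
frequencies of all taxa and their source abundances, m is the single free
parameter, estimated by bounded non-linear least squares.

Two source modes are provided:

- **external** — source abundances are the mean relative abundances in a
  disjoint sample set (the rearing water). The least-squares objective
  uses taxa present in both habitats. Source taxa never detected in any
  local sample carry no information about m and are excluded from the
  objective, but they are kept in the record set and classified: zero
  occupancy at high source abundance is precisely the "selected against /
  dispersal-limited" signal (`include_locally_absent=True` by default;
  the exclusion count is reported either way).
- **self** — the pooled local samples act as their own metacommunity
  (p = mean local relative abundance), the usual protocol when no
  external source is measured. No leave-one-out correction is applied.

### Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| m | migration rate (per-death immigration probability) | fitted | bounded to (1e-6, 1e3), multi-start {m0, 0.01, 0.1, 0.5} |
| N | local community size = reads per sample | post-rarefaction depth | all samples equal after rarefaction |
| d | detection limit (relative abundance) | 1/N | one read at depth N |
| n_boot | bootstrap replicates for the 95% band | 1000 | < 100 triggers a warning record |
| alpha | band tail mass | 0.05 | two-sided |

R² = 1 − SSE/SST of the occupancy curve; it can be negative ("no fit")
and is reported raw. If the observed frequencies are constant, SST = 0
and the fit is flagged degenerate.

### Classification band

The default band is a bootstrap: taxa entering the objective are resampled
with replacement n_boot times, m is refit for each replicate, and at each
taxon's p the predicted frequency of every replicate is pushed through one
binomial draw at the number of local samples, so the band combines
parameter uncertainty with the sampling noise of estimating a frequency
from n_local samples. Band edges are the 2.5/97.5 percentiles of that
simulated distribution, rounded outward to attainable values (the
distribution lives on the 1/n_local grid; interpolated quantiles would
undercover), and always widened to contain the point prediction. A Wilson
score interval on the fitted curve with denominator n_local is available
as the cheaper alternative (`band_method="wilson"`).

Classification is strict: above the band = favoured by selection or a
stronger disperser; below = selected against or dispersal-limited; on the
boundary = neutral (conservative toward the null).

For speed, bootstrap refits evaluate the weighted least-squares objective
for all replicates at once on a 400-point grid over log10 m in [-6, 3]
and refine each minimum by parabolic interpolation; the residual
resolution (< 1% in m) is far below the band's Monte-Carlo noise, and the
refits agree with the reference optimizer in tests.

### Binomial comparison

The neutral fit is compared by AIC against a zero-parameter binomial
sampling model, freq = 1 − (1 − p)^N — local communities as pure random
subsamples of the source, with no drift and no dispersal limitation. Both
AICs use a Gaussian residual likelihood with the ML variance; k = 2 for
the neutral model (m and the residual scale) and k = 1 for the binomial
model. With identical predictions the binomial AIC is lower by exactly 2.

### Known bias of the occupancy approximation

The threshold form `freq = P(x > 1/N)` is an approximation: with counts,
detection is "at least one read", whose exact probability under the
stationary law is beta-binomial, `1 − B(a, b+N)/B(a, b)`. For rare taxa
the exact occupancy is noticeably larger than the threshold value (in the
small-a limit, a·ln(1 + 1/m) versus a smaller exponential-integral-type
quantity), so least squares compensates by inflating m. On exact
neutral-process simulations at this package's study conditions the median
fitted m is ≈ +19% high at m = 0.05 and ≈ +26–32% high at m = 0.3 — and
no alternative constant d repairs both regimes (d = 0.5/N overshoots to
−12% and −30%). The estimator is therefore treated as an *index* of
dispersal: rank order across conditions is recovered reliably (tested),
absolute values inherit the approximation bias. The same misfit is why
slightly fewer than 95% of taxa fall inside the 95% band on neutral data
(~90–97% depending on m).

## Time-decay of similarity

Community similarity S between two samples T hours apart is modelled as
S = c·T^w; the fit is an ordinary least-squares regression of log10 S on
log10 T, so w (the temporal turnover rate) is base-invariant and c is
reported as log10 c. S = 1 − Bray-Curtis for taxonomic turnover and
1 − normalized weighted UniFrac for phylogenetic turnover. Pairs with
T = 0 (log undefined) or S ≤ 0 are excluded and counted, never floored.
Pairs are pooled across ponds by default; a sample filter predicate
restricts the pair set for sensitivity analyses.

## Diversity stack

- Shannon-Wiener in natural log by default (configurable base); Pielou's
  J uses the same base, so J is base-invariant; J is an error below
  richness 2, not a silent 0.
- Faith's PD includes the path to the root of the supplied tree; rooting
  is taken as given in the newick file.
- Weighted UniFrac defaults to the raw branch-weighted form
  Σ l_b |A_b − B_b|; the normalized form (divided by Σ l_b (A_b + B_b))
  is used wherever "1 − distance" must be a similarity in [0, 1]
  (PCoA inputs, time-decay).
- PCoA is classical scaling of −0.5·D² double-centered; axes with
  non-positive eigenvalues are truncated (with a warning record),
  negative eigenvalues are reported, never corrected.
- ANOSIM uses average ranks on ties and R = (r̄_between − r̄_within) /
  (n(n−1)/4), which scales R to [−1, 1] and equals 1 at complete
  separation. The p-value is the add-one permutation tail over seeded
  random label permutations; an exact mode enumerates all orderings for
  small n.
- Rarefaction is a single multivariate-hypergeometric subsample (without
  replacement) per sample; samples below the depth are dropped and
  reported, and the larvae and water tables are rarefied jointly at one
  depth. Detection everywhere afterwards means count ≥ 1.

## Synthetic data

The generators reproduce the study's data-generating assumptions with
known ground truth:

- **Source pool**: lognormal(0, σ) abundances, σ = 1.5 by default — a
  standard long-tailed species-abundance distribution for bacterioplankton.
- **Local communities**: the default "stationary" mode draws a
  composition from Dirichlet(N·m·p) (the stationary law of the
  drift-immigration process; concentration capped at 1e6) and one
  multinomial(N) read sample from it. The "forward" mode runs the
  explicit death-replacement process for 20·N steps from a
  multinomial(N, p) start; it exists to validate the shortcut (their
  occupancy distributions are statistically indistinguishable in tests)
  and is not used routinely.
- **Non-neutral taxa**: injected by occupancy manipulation, because the
  classifier operates on occurrence frequency — above-type taxa from the
  lowest source-abundance decile are forced present in every sample at a
  small constant count, below-type taxa from the top decile are zeroed
  everywhere; sample totals are rebalanced on the most abundant untouched
  taxon so depth stays exact.
- **Succession**: the latent composition follows
  comp[t+1] = (1−r)·comp[t] + r·(fresh lognormal draw), giving pairwise
  similarity that decays with lag (w < 0 for r > 0, w ≈ 0 at r = 0).
- **Full study**: six developmental stages over 350 h with dense-to-sparse
  sampling hours, three ponds per time point, water missing at three
  larvae-only hours, read depth 22,300, S = 500 taxa. Per-stage migration
  rates default to 0.309/0.226/0.042 for the three zoea sub-stages (the
  regime of interest: declining water-to-larvae dispersal after mouth
  opening) and to low values (0.05/0.03/0.02) for nauplius/mysis/
  postlarvae, where exchange with the water is weak.

What the generators do **not** emulate: sequencing error and chimeras,
compositional (primer/extraction) bias, habitat-specific taxon pools (all
taxa exist in the shared source, so at full depth the larvae/water Venn
partition is near-total overlap — unlike real data, where unique taxa
dominate), and phylogenetic signal in abundances (the tree is random, so
phylogenetic turnover is a diluted mirror of taxonomic turnover rather
than an independently structured signal). Passing tests therefore
demonstrate correctness of the estimators on data satisfying the model's
assumptions, not robustness to those real-data artifacts.

## Problem sizes

Tests and the acceptance script run the recovery experiments at
S = 300 taxa, 50 local samples, N = 5000 reads (20 seeds; bands at
n_boot = 1000), model selection at S = 200, 30 samples, N = 2000
(50 replicates per generator), the generator cross-validation at S = 100,
N = 1000, 40 samples, and the full study at S = 500, depth 22,300.
The scaled-down pipeline tests use S = 80, depth 800, n_boot = 120,
99 permutations.

## Known limitations

- Absolute m values inherit the occupancy-approximation bias described
  above; compare m across stages or conditions, not against an absolute
  scale.
- The bootstrap band resamples taxa (not samples) by default; a
  parametric sample-level resampling is available
  (`resample="samples"`) but slower.
- Self mode estimates p from the same samples whose occupancy is fit,
  as is standard practice; the mild circularity is not corrected.
- ANOSIM's permutation p is add-one and hence bounded below by
  1/(n_perm + 1).
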