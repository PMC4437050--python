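# Methods

## Model

A community of fixed size `N` holds `S` partially inter-fertile species
(default diversity levels 3, 5, 10 with initial abundance vectors
{195, 75, 30}, {300, 200, 150, 100, 50} and
{220, 200, 125, 110, 100, 90, 75, 50, 20, 10}; sizes 300, 800, 1000).
Individuals are bisexual, ecologically equivalent and tracked by identity,
species and age. Each reproductive event runs three steps:

1. **Reproduction (simultaneous).** Every individual receives
   `d = round_half_up(PLC × N)` pollen donors sampled uniformly without
   replacement from the other `N − 1` individuals (no spatial structure;
   `d` is capped at `N − 1`). At most `F` (fecundity) crosses are
   attempted; when `d > F`, conspecific donors are attempted first
   (conspecific pollen precedence; a flag switches to a uniform random
   cap). Every attempted conspecific cross yields one viable offspring;
   each attempted heterospecific cross succeeds independently with
   probability `h`; each of the `F − attempted` remaining ovules is selfed,
   succeeding independently with probability `s`. Offspring take the
   mother's species. All viable progeny are pooled into a seed bank that
   exists only within the event.
2. **Mortality.** `round_half_up(m × N)` individuals die, uniformly at
   random, *after* reproducing (the dying contribute to this event's seed
   bank). `m` is fixed at 0.015.
3. **Lottery recruitment.** As many recruits as deaths are drawn uniformly
   without replacement from the seed bank; they enter at age 0 and
   reproduce from the next event. Survivors age by one. If the bank is
   smaller than the death count (possible only at extreme parameter
   corners), everything recruits, the community shrinks, and the event is
   flagged.

Consequences worth noting: richness is monotone non-increasing (no
immigration or speciation, offspring inherit the mother's species); with
`s = h = 0` the community is a neutral-like drift process with positive
frequency dependence (conspecific donor counts scale with own abundance)
and absorbs at monodominance; when `d ≥ F` no ovule is ever left for
selfing, so selfed recruits are structurally impossible.

## Parameters

| parameter | meaning | default / grid |
|---|---|---|
| `plc` | fraction of the community donating pollen to one individual per event | grid {0.01, 0.015, 0.02, 0.025, 0.1, 0.15, 0.25, 0.5} |
| `self_success` (`s`) | per-ovule probability a selfing attempt is viable | grid {0, 0.1, 0.25, 0.4} |
| `hybrid_success` (`h`) | probability a heterospecific cross is viable | grid {0, 0.1, 0.25, 0.4} |
| `fecundity` (`F`) | ovules per individual per event | grid {10, 50, 250} |
| `mortality_rate` (`m`) | per-event random mortality fraction | 0.015 |
| `n_events` | reproductive events per run | 500 |
| `n_replicates` | replicates per parameter combination | 3 |

`F` deliberately understates real tree fecundity by orders of magnitude;
the interesting quantity is the absolute number of viable alternative
offspring, so low `F` makes the selfing/hybridization pathways *harder*
to detect, not easier.

## Numerical design

- **Rounding.** Donor and death counts use round-half-up,
  implemented as `floor(x + 0.5 + 1e-9)`; the guard absorbs binary
  floating-point representation error (0.015 × 300 is stored just below
  4.5 but must give 5).
- **Vectorized engine.** The event loop never materializes individual
  progeny. For each mother the conspecific donor count is hypergeometric
  (uniform sampling without replacement fixes its law), hybrid and selfed
  viable counts are binomial, and lottery recruitment over the pooled
  (species × origin) counts is multivariate hypergeometric. This is
  distribution-identical to composing the per-individual decision tree
  (`reproduce_individual`, which tests exercise directly and cross-check
  against the engine via a naive object-level loop) and keeps a
  1000-individual × 250-ovule × 500-event run under a second.
- **Randomness.** One `numpy` Generator per run, seeded by the run seed;
  draws occur in a fixed order (reproduction in ascending individual id,
  then mortality, then recruitment), so identical (parameters, seed) give
  bit-identical trajectories. Sweep runs derive per-run seeds by hashing
  (base seed, parameter combination, replicate) with blake2b, making
  sweeps resumable, order-independent and parallelizable.
- **Degenerate inputs.** Communities of size < 2 cannot exchange pollen
  (a lone survivor can still self); empty seed banks trigger the shortfall
  path rather than an error; a fully extinct community ends the run with a
  warning.

## Spatial neighborhood analysis

For a stem-mapped plot (`stem_id, x, y, species, genus`; `gx`/`gy`
accepted as aliases), the census counts neighbors within Euclidean
distance ≤ r of a focal stem (boundary inclusive, focal excluded, no
toroidal wrap), their species richness, conspecifics, and congenerics
(same genus, different species). A kd-tree backs the lookup; tests hold it
to an explicit O(n²) distance scan.

Focal trees are selected per congeneric-diversity class (default classes
2, 3, 5–6 and 10–14 species per genus; the edges are an argument), taking
the most abundant qualifying species and sampling stems at least an edge
buffer (default = radius) from every boundary, avoiding edge bias.

The null model asks whether mean neighborhood richness over the focals is
*lower* than expected absent any species–location association: each of
`n_reps` (default 1000) replicates permutes species labels (genus labels
travel along) uniformly over the fixed stem positions — preserving both
the spatial point pattern and the exact abundance multiset — and
recomputes the statistic. One-sided lower-tail p-value with the +1
permutation correction: `p = (1 + #{null ≤ observed}) / (n_reps + 1)`.
A uniform-relocation null is available behind `method="relocate"`.
Validity requires focal selection be independent of labels under the
null; the calibration tests therefore place focals at random interior
stems, and the type-I error at α = 0.05 sits inside binomial 99% bounds
over 200 uniform plots.

## Synthetic plots

`synthetic_plot` generates stem maps carrying the features the analysis
assumes, at any scale a test needs:

- **Abundance skew**: log-series draws scaled to the stem total, with an
  optional head-truncation (`max_relative_abundance`) redistributing
  excess stems down-rank — the "pasoh-like" preset caps the dominant
  species at 2.5% of stems, as in very diverse plots.
- **Genus structure**: quota-based genus sizes matched to target sympatry
  fractions (~19% of species sole in their genus, ~13% with one congener,
  the rest with ≥ 2), shuffled so abundance rank and genus size are
  uncorrelated.
- **Clumping**: a Thomas cluster process per species — uniform parent
  points, Gaussian(σ) offsets, out-of-bounds offsets resampled (not
  clipped) so abundances stay exact. `sigma=None` gives uniform positions
  for null-calibration work.

What the generator does *not* emulate: habitat association, dispersal
anisotropy, size structure (no dbh beyond a placeholder), interactions
between species' point patterns, and real plots' fitted process
parameters. Passing tests on synthetic plots therefore demonstrate the
statistical machinery (calibration, directionality), not any claim about
a particular forest.

## Problem sizes and defaults used in checks

The shipped end-to-end checks run the 3-species community to absorption
(cap 5000 events) and through 500–600 events for the diversity-maintenance
result; Monte Carlo equivalence uses 2 × 10⁴–10⁵ draws; null-model
calibration uses 200 plots of 350 stems with 99 permutations each, chosen
as the smallest sizes at which the binomial bounds are informative. The
acceptance script runs 3 replicates × 600 events.

## Known limitations

- Hybridization here is purely demographic: no genotypes, introgression or
  fitness consequences are tracked, so "hybrid" is an origin tag on an
  otherwise ordinary member of the mother's species.
- Mating is panmictic; there is no spatial pollen kernel, so the simulator
  and the spatial module describe complementary but uncoupled views.
- Recruitment draws without replacement; with banks orders of magnitude
  larger than the death count this is indistinguishable from
  with-replacement sampling, but at shortfall corners the choice matters.
- The diversity-maintenance outcome is stochastic: under the headline
  conditions a minority of seeds lose the rarest species before event 500,
  which is the model's point — variable mating delays extinction rather
  than preventing it.
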