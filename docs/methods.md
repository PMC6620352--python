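# Methods

## The question and the model

Large-bodied frugivores (LBF) — gibbons, macaques, hornbills and large
pigeons, and terrestrial mammals such as deer, elephants and bears — are
the main seed dispersers of many tropical tree species and the main
targets of hunting in Southeast Asia. Because LBF-dispersed tree species
tend to have denser wood than species dispersed by small birds, wind or
unknown agents, their loss is expected to lower the carbon a forest can
hold. `defaunasim` quantifies that expectation for a stem census of a
forest-dynamics plot with a zero-sum stochastic removal–replacement
simulation.

The community is every living stem with dbh ≥ 5 cm (the threshold is
inclusive). Per-stem above-ground biomass uses the moist-forest
allometry

    AGB [kg] = ρ · exp(−1.499 + 2.148 ln D + 0.207 (ln D)² − 0.0281 (ln D)³)

with ρ the species' wood specific gravity (g/cm³) and D the dbh (cm);
above-ground carbon is AGC = AGB / 2. Plot totals are reported in Mg and
Mg/ha. AGB is exactly linear in ρ and strictly increasing in D over the
relevant range, which the test suite checks against an independently
coded transcription.

One simulation replicate under a scenario (which guild is extirpated)
and intensity q ∈ (0, 1]:

1. **Removal.** round(q · N_target) stems of target species are drawn
   uniformly without replacement across the whole plot (per individual,
   not per species; fractional counts round half-to-even, which never
   matters at the canonical 20% steps). The target set is the stems of
   primate-dispersed species (`primates_only`), of any LBF-dispersed
   species (`all_lbf`), or of all species (`control`, removing the same
   *number* of stems as `all_lbf` at that intensity so it isolates any
   procedural artifact).
2. **Replacement.** The community is stratified into four diameter
   classes — [5, 20), [20, 40), [40, 80), [80, ∞) cm (upper-open, so
   80.0 cm is in the largest class) — and each removed stem is replaced
   by a donor drawn uniformly *with* replacement from the non-target
   stems of its own class (for the control, from all non-removed stems).
   The donor pool is fixed at the pre-removal composition. Two options:
   - `wsg_swap`: the removed stem keeps its tag and dbh; only its ρ is
     overwritten by the donor's. The dbh multiset, hence total basal
     area, is conserved bit-for-bit (constant size structure).
   - `full_replace`: the donor's species, dbh and ρ are cloned into the
     removed stem's slot; per-class counts stay fixed but within-class
     size structure may drift.
   Either way N_T and every per-class count are exactly constant — the
   zero-sum assumption.
3. **Statistic.** ΔAGC% = 100 · (AGC_sim − AGC_obs) / AGC_obs.

The experiment grid is 3 scenarios × 5 intensities (0.2 … 1.0) × 2
options. Each cell runs 200 replicates; the point estimate is their
mean, and the 95% CI is the 2.5/97.5 percentile interval of 200
bootstrap resamples of the replicate vector (statistic = mean). A
heavier `bootstrap_mode="rerun"` re-runs the whole replicate procedure
per bootstrap draw instead; for the default community sizes the two
agree closely and the resampling form is the default.

Reproducibility: one master seed; replicate r of stream s uses the RNG
substream (seed, s, r), so results are bit-identical for a given seed
and replicate r does not change when n_reps grows.

## Trait statistics and imputation

Trait comparisons are species-level (one WSG and one maximum attained
dbh per species, the maximum taken after the ≥ 5 cm filter): Welch
two-sample t-tests (pooled-variance Student available by flag) of each
trait between LBF-dispersed species and the rest, and between
primate-dispersed species and the rest. Positive t means the focal
guild has the larger mean; group medians are reported descriptively
alongside.

Missing WSG values are imputed with the precedence species-level
database value → local field sample → genus median → family median,
medians computed over the reference database's species-level values
(mean aggregation available by flag); the provenance of every value is
recorded. A species with no value at any level is a hard error.

For the carbon-share breakdown each species is assigned to exactly one
category with priority P > TB > O: P if any agent is a primate (gibbon
or macaque), else TB if any agent is a hornbill/large pigeon or
terrestrial mammal, else O. An alternative reading in which P counts
only species dispersed by primates *alone* is available
(`primates_alone=True`). The simulation target sets do not use this
priority; they use the guild predicates directly, so the all-LBF target
set is always a superset of the primate target set. "Unknown animals"
and "unclassified" never count as LBF: the guild is an explicit
whitelist.

## The synthetic-data generator

The generator emulates the statistical structure the analysis needs, so
the pipeline runs and is testable without any plot download. Defaults
echo a 30-ha seasonal evergreen plot: 232 species, 33,844 stems ≥ 5 cm.

- **Abundances**: per-species weights drawn i.i.d. from a log-series
  distribution (Fisher's x derived from α = 35 and the stem count),
  normalized, then a multinomial allocation with one stem per species
  forced. This produces a log-series-like rank-abundance curve with
  realistic dominance, not an exact conditional Fisher sample. A
  lognormal alternative is available.
- **Diameters**: truncated power-law on [5, 150] cm with exponent 2,
  i.i.d. across stems and independent of species — a deliberate
  simplification (real species differ in size structure).
- **Dispersal groups**: independent per-group Bernoulli inclusion per
  species over the eight agent groups, redrawn while empty. Default
  inclusion probabilities are small-bird-dominated with the four LBF
  groups at 0.05–0.06 each, chosen so that after the empty-set redraw
  the LBF guild covers ~30% of species and (with the WSG shift) about a
  third of plot carbon on average — the coarse regime of the motivating
  system. They are not calibrated to reproduce any published number.
- **WSG**: one species-level draw from Normal(0.55 + δ·1[LBF], 0.12)
  truncated to (0.1, 1.2) g/cm³, default δ = 0.06 — the guild trait
  contrast that drives the predicted carbon loss. δ = 0 gives the null
  world; δ may be negative.

What the generator does *not* emulate: spatial structure (coordinates
are optional and uniform), species-specific size distributions,
phylogenetic correlation of traits, multi-census dynamics, and any
dependence of abundance on traits. Passing tests on synthetic data
therefore validate the machinery and the qualitative mechanism, not the
magnitude of any real plot's carbon response.

## Conditioning of the null calibration

With species-level traits, a *single* realized community has a nonzero
target-vs-pool WSG imbalance even at δ = 0 (a handful of dominant
species carry much of the carbon), so its mean ΔAGC% under guild removal
is a draw with an across-realization sd of several percentage points —
orders of magnitude larger than the bootstrap SE over replicates.
Likewise the control's mean deviates slightly from zero on a fixed
community through the realized within-class association of stem size
with WSG (the swap preserves class WSG means, but carbon weighs WSG by
the allometric shape factor); the familiar "slight increase in biomass"
of control runs is exactly this finite-sample effect, and its sign is
not reproducible. Unbiasedness of the machinery is therefore tested two
ways: paired against the closed-form expectation of the swap on each
community (which isolates sampling-implementation error to ~0.01 pp),
and as grand means across many independent community realizations.

## Numerical and design choices

- Removal counts: `np.rint` (half-to-even); errors if a requested count
  exceeds the pool (impossible for q ≤ 1 on non-control scenarios).
- A diameter class with no donor candidates raises an error naming the
  class rather than silently re-using target stems.
- Sums are plain float64 accumulation; conservation identities
  (category totals vs plot total) hold to ~1e-12 relative and exact
  where the operation is exact (basal area under `wsg_swap`).
- Strict species resolution by default: a census species missing from
  the trait table aborts the run (silent drops would bias AGC totals);
  an explicit drop-and-log mode exists.
- Censuses are one row per living main stem; multi-stem individuals are
  treated as independent stems (per-stem AGB), the convention the
  allometry expects.
- CSV is the interchange format; foreign column names map through a
  small YAML dialect file. Group codes serialize as sorted
  pipe-delimited lists, so write→read round-trips are exact.

## Problem sizes used in the test suite

The acceptance-style tests run on synthetic communities of 2,000 stems
(conservation sweep over 50 seeds), 20,000 stems (null calibration over
40–160 community realizations; intensity monotonicity with 2,000
replicates per intensity) and the full 33,844-stem default (grid
cardinality and seed reproducibility at 50 replicates / 50 bootstraps);
`scripts/acceptance.py` runs the full default community at 200
replicates / 200 bootstraps. These sizes were chosen as the package's
own balance of statistical resolution against a test run a maintainer
will actually wait for.

## Known limitations

- Community equilibrium only: no transient dynamics, mortality,
  recruitment, density dependence, or secondary-dispersal compensation.
- The replacement pool is the present-day non-target community; no
  immigration of species not in the census.
- Whether full replacement should sample within diameter classes or
  community-wide is ecologically arguable; within-class is the default
  (it is what keeps the size structure comparable), community-wide is a
  switch.
- The t-tests carry no multiple-testing correction and no phylogenetic
  correction; the unit of analysis is the species, unweighted by
  abundance.
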