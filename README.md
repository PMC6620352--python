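# defaunasim

How much above-ground carbon does a tropical forest stand to lose when
its large-bodied frugivores (LBF) — gibbons, macaques, hornbills and
large pigeons, terrestrial mammals — are hunted out, and with them the
tree species that depend on those animals for seed dispersal?

`defaunasim` answers this for a ForestGEO-style stem census with a
zero-sum stochastic removal–replacement simulation. It is a Python
library for ecologists working with forest-dynamics-plot data: you load
(or synthesize) a census and a species-trait table, and the package
classifies species by seed-disperser guild, computes per-stem carbon
from a wood-density allometry, and simulates defaunation scenarios with
bootstrap confidence intervals.

## The model in brief

Per-stem above-ground biomass (kg) for trees with dbh ≥ 5 cm:

```
AGB = ρ · exp(−1.499 + 2.148 ln D + 0.207 (ln D)² − 0.0281 (ln D)³)
```

with ρ = wood specific gravity (g/cm³) and D = dbh (cm); carbon is
AGC = AGB/2. A simulation replicate removes a fraction *q* (20–100%) of
the stems of target species — primate-dispersed, all LBF-dispersed, or
any species (control, same removal count as the all-LBF case) — and
replaces each removed stem from the non-target community within its
diameter class ([5,20), [20,40), [40,80), [80,∞) cm), so the total stem
count N_T and every class count are held constant (zero-sum). Two
replacement options: `wsg_swap` keeps each removed stem's size and only
swaps its wood density (basal area exactly conserved), `full_replace`
clones the donor entirely. The headline statistic is
ΔAGC% = 100·(AGC_sim − AGC_obs)/AGC_obs, averaged over 200 replicates,
with a 95% percentile-bootstrap CI (200 resamples). Because
LBF-dispersed species tend to have denser wood, ΔAGC% is negative.

## Worked example

Scripts under `examples/` each run one capability end to end. With the
built-in synthetic 30-ha community (232 species, 33,844 stems, seed 1):

```
$ python examples/04_defaunation_experiment.py
complete defaunation (intensity 1.0):
     scenario       option  mean_dagc_pct  ci_low  ci_high
      all_lbf     wsg_swap          -3.41   -3.45    -3.37
      all_lbf full_replace          -3.41   -3.47    -3.34
primates_only     wsg_swap          -1.47   -1.49    -1.44
primates_only full_replace          -1.39   -1.44    -1.34
      control     wsg_swap           0.06   -0.00     0.12
      control full_replace           0.09   -0.03     0.21
```

Read: extirpating every LBF-dispersed individual and letting the rest
of the community fill the space costs ~3.4% of plot carbon on this
community; losing only the primates costs ~1.5%; the control rows sit
at zero within noise, so the loss is the guild's wood-density signal,
not a procedural artifact. `examples/02_carbon_shares.py` prints the
carbon share at stake (P 15.2%, TB 22.3% on this community — LBF
guild ≈ 37%), and `examples/03_trait_comparisons.py` the species-level
Welch t-tests behind the mechanism (WSG: t = 3.89, p < 0.001; maximum
size: t = −0.04, n.s.).

From Python the same run is:

```python
from defaunasim import SynthConfig, generate, ExperimentConfig, run_experiment

census, traits = generate(SynthConfig(seed=1))
summaries = run_experiment(census, traits, ExperimentConfig(seed=1))
```

Real data drop in via `read_census` / `read_traits` (plain CSV, column
names mappable through a YAML dialect file) plus `impute_wsg` for
species missing wood-density values. A thin CLI mirrors the examples:
`defaunasim synth|shares|traits|simulate` (see `--help`), writing CSV
outputs and a reproducibility manifest per run.

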