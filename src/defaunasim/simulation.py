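"""Zero-sum defaunation simulation.

The model removes a fraction (the defaunation intensity, 20–100%) of the
stems belonging to tree species dispersed by the targeted frugivore guild
and replaces each removed stem with a draw from the remaining community,
keeping the total stem count N_T — and the stem count within each of four
diameter classes (5–20, 20–40, 40–80, >80 cm) — exactly constant.

Two replacement options bracket the ecological assumptions:

* ``wsg_swap``     — the removed stem keeps its size; only its wood
  specific gravity is overwritten by that of a random same-class donor,
  so basal area is conserved exactly (constant size structure);
* ``full_replace`` — the removed stem is replaced by a clone (species,
  dbh, WSG) of a random same-class donor, so size structure within a
  class may drift while per-class counts stay fixed.

Three scenarios: ``primates_only`` (gibbon + macaque), ``all_lbf`` (the
whole large-bodied frugivore guild), and ``control`` (stems of any species
removed, in the same number as the all-LBF scenario at that intensity).
The headline statistic per replicate is
``dAGC% = 100 * (AGC_sim - AGC_obs) / AGC_obs``;  the point estimate is
the mean over replicates and the 95% CI comes from a percentile bootstrap
of the replicate vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import biomass
from .classification import lbf_mask, primate_mask

__all__ = [
    "SIZE_CLASS_EDGES",
    "assign_size_class",
    "CommunityState",
    "build_community",
    "Scenario",
    "ExperimentConfig",
    "SimulationSummary",
    "select_removals",
    "replace_wsg_swap",
    "replace_full",
    "run_replicates",
    "bootstrap_ci",
    "BootstrapResult",
    "run_experiment",
    "summaries_to_frame",
]

#: inner edges of the four diameter classes; intervals are upper-open,
#: [5,20), [20,40), [40,80), [80,inf)
SIZE_CLASS_EDGES = (20.0, 40.0, 80.0)

SCENARIOS = ("all_lbf", "primates_only", "control")
OPTIONS = ("wsg_swap", "full_replace")


def assign_size_class(dbh):
    """Diameter class 1–4 for dbh >= 5 cm; vectorizes over arrays."""
    d = np.asarray(dbh, dtype=float)
    if np.any(d < 5):
        raise ValueError("size classes are defined for dbh >= 5 cm only")
    return np.digitize(d, SIZE_CLASS_EDGES) + 1


@dataclass
class CommunityState:
    """Per-stem arrays of the community under simulation.

    ``shape`` is the diameter-only allometry factor, so each stem's AGB is
    ``shape * wsg`` (kg).  ``is_lbf`` / ``is_primate`` mark stems whose
    species is dispersed by the corresponding guild.
    """

    tag: np.ndarray
    species: np.ndarray
    dbh: np.ndarray
    wsg: np.ndarray
    shape: np.ndarray
    size_class: np.ndarray
    is_lbf: np.ndarray
    is_primate: np.ndarray

    @property
    def n_t(self) -> int:
        return len(self.dbh)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.size_class, minlength=5)[1:]

    def agc_mg(self) -> float:
        """Total above-ground carbon, Mg (AGB/2, kg -> Mg)."""
        return 0.5 * float(self.shape @ self.wsg) / biomass.KG_PER_MG

    def basal_area(self) -> float:
        """Total basal area, m^2 (pi/4 * dbh^2, cm^2 -> m^2)."""
        return float(np.pi / 4.0 * np.sum(self.dbh**2)) / 1e4

    def copy(self) -> "CommunityState":
        return CommunityState(
            *(a.copy() for a in (self.tag, self.species, self.dbh, self.wsg,
                                 self.shape, self.size_class, self.is_lbf, self.is_primate))
        )


def build_community(
    census: pd.DataFrame, traits: pd.DataFrame, min_dbh: float = 5.0
) -> CommunityState:
    """Join census stems with species traits into a simulation-ready state.

    Applies the dbh filter, resolves per-stem WSG and guild membership, and
    pre-computes the allometry shape factor once per stem.
    """
    from .io import filter_min_dbh

    census = filter_min_dbh(census, min_dbh)
    idx = traits.set_index("species")
    missing = sorted(set(census["species"]) - set(idx.index))
    if missing:
        raise ValueError(f"species missing from trait table: {', '.join(missing[:10])}")
    wsg = idx["wsg"].reindex(census["species"]).to_numpy(float)
    if np.isnan(wsg).any():
        bad = sorted(census["species"][np.isnan(wsg)].unique())
        raise ValueError(f"species with missing WSG (impute first): {', '.join(bad[:10])}")
    lbf = pd.Series(lbf_mask(traits).to_numpy(), index=traits["species"])
    prim = pd.Series(primate_mask(traits).to_numpy(), index=traits["species"])
    dbh = census["dbh"].to_numpy(float)
    return CommunityState(
        tag=census["tag"].to_numpy(object),
        species=census["species"].to_numpy(object),
        dbh=dbh,
        wsg=wsg,
        shape=biomass.agb_shape(dbh),
        size_class=assign_size_class(dbh),
        is_lbf=lbf.reindex(census["species"]).to_numpy(bool),
        is_primate=prim.reindex(census["species"]).to_numpy(bool),
    )


@dataclass(frozen=True)
class Scenario:
    """One removal rule: which guild is extirpated, how hard, and how
    removed stems are replaced."""

    name: str  # all_lbf | primates_only | control
    intensity: float
    option: str = "wsg_swap"  # wsg_swap | full_replace

    def __post_init__(self):
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIOS}")
        if self.option not in OPTIONS:
            raise ValueError(f"unknown option {self.option!r}; choose from {OPTIONS}")
        if not (0.0 < self.intensity <= 1.0):
            raise ValueError("intensity must be in (0, 1]")


def _target_mask(state: CommunityState, name: str) -> np.ndarray:
    if name == "all_lbf":
        return state.is_lbf
    if name == "primates_only":
        return state.is_primate
    return np.ones(state.n_t, dtype=bool)  # control: any stem may be removed


def _pool_mask(state: CommunityState, name: str) -> np.ndarray:
    # Donors come from the untargeted remainder of the community; the
    # control scenario has no untargeted guild, so its donors are all stems.
    if name == "control":
        return np.ones(state.n_t, dtype=bool)
    return ~_target_mask(state, name)


def _removal_count(state: CommunityState, scenario: Scenario) -> int:
    # Control removes the same NUMBER of stems as the all-LBF scenario
    # at that intensity; fractional counts round half-to-even.
    basis = "all_lbf" if scenario.name == "control" else scenario.name
    n_basis = int(_target_mask(state, basis).sum())
    return int(np.rint(scenario.intensity * n_basis))


def select_removals(
    state: CommunityState, scenario: Scenario, rng: np.random.Generator
) -> np.ndarray:
    """Indices of stems removed in one replicate.

    Drawn uniformly without replacement over all target stems (per
    individual, not per species).
    """
    target = np.flatnonzero(_target_mask(state, scenario.name))
    n_remove = _removal_count(state, scenario)
    if scenario.name != "control" and target.size == 0 and n_remove > 0:
        raise ValueError(f"scenario {scenario.name!r} has an empty target set")
    if n_remove > target.size:
        raise ValueError(
            f"removal count {n_remove} exceeds the {target.size}-stem target pool"
        )
    if n_remove == 0:
        return np.empty(0, dtype=np.intp)
    return rng.choice(target, size=n_remove, replace=False)


def _sample_donors(
    state: CommunityState,
    removals: np.ndarray,
    pool: np.ndarray,
    rng: np.random.Generator,
    by_class: bool = True,
) -> np.ndarray:
    """One donor stem index per removed stem, with replacement from the
    (pre-removal) pool, stratified by diameter class unless ``by_class``
    is off."""
    donors = np.empty(removals.size, dtype=np.intp)
    if not by_class:
        cand = np.flatnonzero(pool)
        if cand.size == 0:
            raise ValueError("replacement pool is empty")
        donors[:] = rng.choice(cand, size=removals.size, replace=True)
        return donors
    rem_class = state.size_class[removals]
    for c in np.unique(rem_class):
        sel = rem_class == c
        cand = np.flatnonzero(pool & (state.size_class == c))
        if cand.size == 0:
            raise ValueError(f"no replacement candidates in diameter class {c}")
        donors[sel] = rng.choice(cand, size=int(sel.sum()), replace=True)
    return donors


def replace_wsg_swap(
    state: CommunityState,
    removals: np.ndarray,
    rng: np.random.Generator,
    pool: np.ndarray | None = None,
) -> CommunityState:
    """Swap each removed stem's WSG for a same-class donor's WSG.

    Tags, species identities and the dbh multiset are untouched, so basal
    area and per-class counts are conserved exactly.
    """
    new = state.copy()
    if removals.size == 0:
        return new
    if pool is None:
        pool = ~np.isin(np.arange(state.n_t), removals)
    donors = _sample_donors(state, removals, pool, rng, by_class=True)
    new.wsg[removals] = state.wsg[donors]
    return new


def replace_full(
    state: CommunityState,
    removals: np.ndarray,
    rng: np.random.Generator,
    pool: np.ndarray | None = None,
    by_class: bool = True,
) -> CommunityState:
    """Replace each removed stem with a clone of a same-class donor.

    The removed stem's tag (its slot in the plot) is kept; species, dbh,
    WSG and guild flags are copied from the donor.  Per-class counts are
    conserved when ``by_class`` is on (the default).
    """
    new = state.copy()
    if removals.size == 0:
        return new
    if pool is None:
        pool = ~np.isin(np.arange(state.n_t), removals)
    donors = _sample_donors(state, removals, pool, rng, by_class=by_class)
    for arr_new, arr_old in (
        (new.species, state.species),
        (new.dbh, state.dbh),
        (new.wsg, state.wsg),
        (new.shape, state.shape),
        (new.size_class, state.size_class),
        (new.is_lbf, state.is_lbf),
        (new.is_primate, state.is_primate),
    ):
        arr_new[removals] = arr_old[donors]
    return new


def _one_replicate(
    state: CommunityState,
    scenario: Scenario,
    rng: np.random.Generator,
    agc_obs: float,
    full_replace_by_class: bool = True,
) -> float:
    removals = select_removals(state, scenario, rng)
    pool = _pool_mask(state, scenario.name)
    if scenario.name == "control":
        # donors must not be the very stems being removed this replicate
        pool = pool.copy()
        pool[removals] = False
    if scenario.option == "wsg_swap":
        sim = replace_wsg_swap(state, removals, rng, pool=pool)
    else:
        sim = replace_full(state, removals, rng, pool=pool, by_class=full_replace_by_class)
    return 100.0 * (sim.agc_mg() - agc_obs) / agc_obs


def run_replicates(
    state: CommunityState,
    scenario: Scenario,
    n_reps: int = 200,
    master_seed: int = 0,
    stream: int = 0,
    full_replace_by_class: bool = True,
) -> np.ndarray:
    """dAGC% for ``n_reps`` independent replicates.

    Each replicate gets its own RNG substream derived from
    ``(master_seed, stream, replicate)``, so replicate r is reproducible
    and independent of ``n_reps``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    agc_obs = state.agc_mg()
    out = np.empty(n_reps, dtype=float)
    for r in range(n_reps):
        rng = np.random.default_rng(np.random.SeedSequence([master_seed, stream, r]))
        out[r] = _one_replicate(state, scenario, rng, agc_obs, full_replace_by_class)
    return out


@dataclass(frozen=True)
class BootstrapResult:
    mean: float
    ci_low: float
    ci_high: float
    se: float
    n_boot: int


def bootstrap_ci(
    replicates: np.ndarray,
    n_boot: int = 200,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Percentile bootstrap of the replicate mean.

    Resamples the replicate vector (same size, with replacement) ``n_boot``
    times; the CI is the (alpha/2, 1-alpha/2) percentile interval of the
    bootstrap means, the point estimate is the plain mean, and ``se`` is
    the standard deviation of the bootstrap means.
    """
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 replicate values to bootstrap")
    if rng is None:
        rng = np.random.default_rng()
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    boot_means = x[idx].mean(axis=1)
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(boot_means, [alpha, 100.0 - alpha])
    return BootstrapResult(
        mean=float(x.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        se=float(boot_means.std(ddof=1)),
        n_boot=n_boot,
    )


@dataclass(frozen=True)
class SimulationSummary:
    scenario: str
    intensity: float
    option: str
    mean_dagc_pct: float
    ci_low: float
    ci_high: float
    se_boot: float
    n_reps: int
    n_boot: int
    seed: int


@dataclass
class ExperimentConfig:
    """Full factorial experiment definition (scenarios x intensities x
    replacement options) plus Monte Carlo sizes and the master seed."""

    scenarios: Sequence[str] = SCENARIOS
    intensities: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0)
    options: Sequence[str] = OPTIONS
    n_reps: int = 200
    n_boot: int = 200
    seed: int = 0
    plot_area_ha: float = 30.0
    min_dbh: float = 5.0
    ci_level: float = 0.95
    bootstrap_mode: str = "resample"  # resample | rerun
    full_replace_by_class: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        from .io import load_yaml_config

        return cls.from_dict(load_yaml_config(path))


def run_experiment(
    census: pd.DataFrame,
    traits: pd.DataFrame,
    config: ExperimentConfig | None = None,
    keep_replicates: bool = False,
):
    """Run the full scenario grid and summarize each cell.

    Returns a list of :class:`SimulationSummary` (one per scenario x
    intensity x option) and, if ``keep_replicates``, a dict mapping
    ``(scenario, intensity, option)`` to the replicate dAGC% vector.
    """
    cfg = config or ExperimentConfig()
    state = build_community(census, traits, min_dbh=cfg.min_dbh)
    combos = list(itertools.product(cfg.scenarios, cfg.options, cfg.intensities))
    summaries: list[SimulationSummary] = []
    replicates: dict = {}
    for stream, (name, option, intensity) in enumerate(combos):
        scenario = Scenario(name=name, intensity=intensity, option=option)
        reps = run_replicates(
            state,
            scenario,
            n_reps=cfg.n_reps,
            master_seed=cfg.seed,
            stream=stream,
            full_replace_by_class=cfg.full_replace_by_class,
        )
        if cfg.bootstrap_mode == "rerun":
            # heavier reading: n_boot independent re-runs of the whole
            # replicate procedure; CI from the distribution of run means
            means = np.empty(cfg.n_boot)
            for b in range(cfg.n_boot):
                rb = run_replicates(
                    state, scenario, n_reps=cfg.n_reps, master_seed=cfg.seed,
                    stream=10_000 + stream * 1_000 + b,
                    full_replace_by_class=cfg.full_replace_by_class,
                )
                means[b] = rb.mean()
            alpha = 100.0 * (1.0 - cfg.ci_level) / 2.0
            lo, hi = np.percentile(means, [alpha, 100.0 - alpha])
            boot = BootstrapResult(float(reps.mean()), float(lo), float(hi),
                                   float(means.std(ddof=1)), cfg.n_boot)
        else:
            brng = np.random.default_rng(np.random.SeedSequence([cfg.seed, stream, 2**30]))
            boot = bootstrap_ci(reps, n_boot=cfg.n_boot, level=cfg.ci_level, rng=brng)
        summaries.append(
            SimulationSummary(
                scenario=name,
                intensity=intensity,
                option=option,
                mean_dagc_pct=boot.mean,
                ci_low=boot.ci_low,
                ci_high=boot.ci_high,
                se_boot=boot.se,
                n_reps=cfg.n_reps,
                n_boot=cfg.n_boot,
                seed=cfg.seed,
            )
        )
        if keep_replicates:
            replicates[(name, intensity, option)] = reps
    if keep_replicates:
        return summaries, replicates
    return summaries


def summaries_to_frame(summaries: Sequence[SimulationSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])
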