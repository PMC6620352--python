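import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from defaunasim import simulation as sim
from defaunasim import build_community, two_wsg_toy
from defaunasim.classification import DispersalGroup


def make_community(species_stems, groups, wsgs):
    """Hand-built (census, traits): species_stems maps code -> list of dbh."""
    rows = []
    i = 0
    for code, dbhs in species_stems.items():
        for d in dbhs:
            rows.append({"tag": f"T{i:04d}", "species": code, "dbh": float(d)})
            i += 1
    census = pd.DataFrame(rows)
    traits = pd.DataFrame(
        {
            "species": list(species_stems),
            "genus": "G",
            "family": "F",
            "wsg": [wsgs[c] for c in species_stems],
            "wsg_source": "species_db",
            "dispersal_groups": [
                frozenset(DispersalGroup(g) for g in groups[c]) for c in species_stems
            ],
        }
    )
    return census, traits


class TestSizeClass:
    @pytest.mark.parametrize(
        "dbh, cls",
        [(5.0, 1), (19.999, 1), (20.0, 2), (39.99, 2), (40.0, 3), (79.9, 3), (80.0, 4), (300.0, 4)],
    )
    def test_half_open_bounds(self, dbh, cls):
        assert sim.assign_size_class(dbh) == cls

    def test_below_filter_rejected(self):
        with pytest.raises(ValueError):
            sim.assign_size_class(4.9)

    @given(st.floats(min_value=5.0, max_value=500.0))
    def test_every_stem_maps_to_exactly_one_class(self, dbh):
        assert sim.assign_size_class(dbh) in (1, 2, 3, 4)


class TestSelectRemovals:
    @pytest.fixture()
    def state(self):
        census, traits = make_community(
            {"LBF1": [10.0] * 10, "OTH": [10.0] * 20},
            {"LBF1": ["gibbon"], "OTH": ["wind"]},
            {"LBF1": 0.8, "OTH": 0.6},
        )
        return build_community(census, traits)

    def test_full_intensity_removes_every_target(self, state, rng):
        removed = sim.select_removals(state, sim.Scenario("all_lbf", 1.0), rng)
        assert len(removed) == 10
        assert state.is_lbf[removed].all()

    def test_partial_intensity_exact_fraction(self, state, rng):
        removed = sim.select_removals(state, sim.Scenario("all_lbf", 0.4), rng)
        assert len(removed) == 4

    def test_fractional_count_rounds_half_even(self, rng):
        census, traits = make_community(
            {"LBF1": [10.0] * 7, "OTH": [10.0] * 5},
            {"LBF1": ["macaque"], "OTH": ["wind"]},
            {"LBF1": 0.8, "OTH": 0.6},
        )
        state = build_community(census, traits)
        removed = sim.select_removals(state, sim.Scenario("all_lbf", 0.4), rng)
        assert len(removed) == 3  # round-half-even of 2.8

    def test_control_count_matches_all_lbf_count(self, state, rng):
        for intensity in (0.2, 0.6, 1.0):
            n_lbf = len(sim.select_removals(state, sim.Scenario("all_lbf", intensity), rng))
            ctrl = sim.select_removals(state, sim.Scenario("control", intensity), rng)
            assert len(ctrl) == n_lbf

    def test_control_may_remove_any_species(self, state, rng):
        hits = set()
        for r in range(30):
            ctrl = sim.select_removals(
                state, sim.Scenario("control", 1.0), np.random.default_rng(r)
            )
            hits.update(np.asarray(state.species[ctrl]))
        assert hits == {"LBF1", "OTH"}

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            sim.Scenario("everything", 0.5)
        with pytest.raises(ValueError):
            sim.Scenario("all_lbf", 0.0)
        with pytest.raises(ValueError):
            sim.Scenario("all_lbf", 0.5, option="teleport")


class TestReplacement:
    @pytest.fixture()
    def two_class_state(self):
        census, traits = make_community(
            {"LBF1": [10.0, 12.0, 25.0, 30.0], "OTH1": [11.0, 26.0], "OTH2": [9.0, 33.0]},
            {"LBF1": ["gibbon"], "OTH1": ["wind"], "OTH2": ["smaller_birds"]},
            {"LBF1": 0.8, "OTH1": 0.6, "OTH2": 0.6},
        )
        return build_community(census, traits)

    def test_swap_single_value_pool_deterministic(self, two_class_state, rng):
        state = two_class_state
        removals = np.flatnonzero(state.is_lbf)
        new = sim.replace_wsg_swap(state, removals, rng, pool=~state.is_lbf)
        assert np.all(new.wsg[removals] == 0.6)

    def test_swap_preserves_dbh_multiset_and_basal_area(self, two_class_state, rng):
        state = two_class_state
        removals = np.flatnonzero(state.is_lbf)
        new = sim.replace_wsg_swap(state, removals, rng, pool=~state.is_lbf)
        assert np.array_equal(new.dbh, state.dbh)
        assert new.basal_area() == state.basal_area()  # bit-identical
        assert np.array_equal(new.class_counts(), state.class_counts())

    def test_full_replacement_clones_within_class(self, two_class_state, rng):
        state = two_class_state
        removals = np.flatnonzero(state.is_lbf)
        new = sim.replace_full(state, removals, rng, pool=~state.is_lbf)
        assert np.array_equal(new.class_counts(), state.class_counts())
        assert new.size_class[removals].tolist() == state.size_class[removals].tolist()
        assert not new.is_lbf[removals].any()  # clones come from the pool

    def test_empty_removals_leave_state_unchanged(self, two_class_state, rng):
        state = two_class_state
        empty = np.empty(0, dtype=np.intp)
        for op in (sim.replace_wsg_swap, sim.replace_full):
            new = op(state, empty, rng)
            assert np.array_equal(new.wsg, state.wsg)
            assert np.array_equal(new.dbh, state.dbh)

    def test_class_without_donors_errors_naming_class(self, rng):
        census, traits = make_community(
            {"LBF1": [10.0, 85.0], "OTH": [10.0]},  # class 4 has only a target stem
            {"LBF1": ["gibbon"], "OTH": ["wind"]},
            {"LBF1": 0.8, "OTH": 0.6},
        )
        state = build_community(census, traits)
        removals = np.flatnonzero(state.is_lbf)
        with pytest.raises(ValueError, match="class 4"):
            sim.replace_wsg_swap(state, removals, rng, pool=~state.is_lbf)


class TestRunReplicates:
    def test_toy_closed_form_every_replicate(self, toy):
        census, traits = toy
        state = build_community(census, traits)
        reps = sim.run_replicates(state, sim.Scenario("all_lbf", 1.0, "wsg_swap"),
                                  n_reps=20, master_seed=1)
        expected = 100.0 * (0.6 - 0.8) / (0.8 + 0.6)
        np.testing.assert_allclose(reps, expected, rtol=1e-9)

    def test_toy_equal_densities_exactly_zero(self):
        census, traits = two_wsg_toy(w_l=0.6, w_o=0.6)
        state = build_community(census, traits)
        reps = sim.run_replicates(state, sim.Scenario("all_lbf", 1.0, "wsg_swap"),
                                  n_reps=10, master_seed=1)
        assert np.all(reps == 0.0)

    def test_zero_sum_invariants_hold_for_all_options(self, small_community, rng):
        census, traits = small_community
        state = build_community(census, traits)
        for name in ("all_lbf", "primates_only", "control"):
            for option in ("wsg_swap", "full_replace"):
                scenario = sim.Scenario(name, 0.6, option)
                removals = sim.select_removals(state, scenario, rng)
                pool = (
                    ~state.is_lbf if name == "all_lbf"
                    else ~state.is_primate if name == "primates_only"
                    else None
                )
                op = sim.replace_wsg_swap if option == "wsg_swap" else sim.replace_full
                new = op(state, removals, rng, pool=pool)
                assert new.n_t == state.n_t
                assert np.array_equal(new.class_counts(), state.class_counts())

    def test_replicate_stream_invariant_to_n_reps(self, small_community):
        census, traits = small_community
        state = build_community(census, traits)
        scenario = sim.Scenario("all_lbf", 0.4, "full_replace")
        short = sim.run_replicates(state, scenario, n_reps=5, master_seed=9)
        long = sim.run_replicates(state, scenario, n_reps=12, master_seed=9)
        np.testing.assert_array_equal(short, long[:5])

    def test_mirrored_null_unbiased_all_scenarios_options(self):
        # target and pool empirically identical: each LBF species has a
        # non-LBF twin with the same WSG and the same stem diameters
        rng0 = np.random.default_rng(5)
        stems, groups, wsgs = {}, {}, {}
        for k in range(8):
            dbhs = rng0.uniform(5, 90, size=30)
            w = rng0.uniform(0.4, 0.9)
            stems[f"L{k}"] = dbhs
            stems[f"O{k}"] = dbhs.copy()
            groups[f"L{k}"] = ["gibbon" if k % 2 else "terrestrial_mammals"]
            groups[f"O{k}"] = ["wind"]
            wsgs[f"L{k}"] = w
            wsgs[f"O{k}"] = w
        census, traits = make_community(stems, groups, wsgs)
        state = build_community(census, traits)
        for name in ("all_lbf", "control"):
            for option in ("wsg_swap", "full_replace"):
                reps = sim.run_replicates(
                    state, sim.Scenario(name, 1.0, option), n_reps=120, master_seed=3
                )
                se = reps.std(ddof=1) / np.sqrt(len(reps))
                assert abs(reps.mean()) < 3 * max(se, 1e-12), (name, option)

    def test_guild_ordering_when_nonprimate_lbf_carry_dense_wood(self):
        # hornbill-dispersed species denser than the pool: extirpating the
        # whole guild must cost at least as much carbon as primates alone
        census, traits = make_community(
            {"PRI": [15.0] * 10, "HORN": [15.0] * 10, "WIND": [15.0] * 10},
            {"PRI": ["gibbon"], "HORN": ["hornbills_large_pigeons"], "WIND": ["wind"]},
            {"PRI": 0.8, "HORN": 0.9, "WIND": 0.6},
        )
        state = build_community(census, traits)
        means = {}
        for name in ("all_lbf", "primates_only"):
            reps = sim.run_replicates(state, sim.Scenario(name, 1.0, "wsg_swap"),
                                      n_reps=100, master_seed=2)
            means[name] = reps.mean()
        # all-LBF pool is the single wind species -> deterministic run
        assert means["all_lbf"] == pytest.approx(100 * (1.8 - 2.3) / 2.3, rel=1e-9)
        # primates-only pool mixes hornbill (0.9) and wind (0.6) donors;
        # expected donor density 0.75, MC noise sd ~0.21 pp on the mean
        assert means["primates_only"] == pytest.approx(100 * (0.75 - 0.8) * 10 / 23, abs=0.7)
        assert means["all_lbf"] <= means["primates_only"]


class TestBootstrap:
    def test_constant_vector_degenerate_interval(self, rng):
        res = sim.bootstrap_ci(np.full(50, 3.14), n_boot=100, rng=rng)
        assert res.mean == res.ci_low == res.ci_high == pytest.approx(3.14)
        assert res.se == 0.0

    def test_interval_ordering(self, rng):
        res = sim.bootstrap_ci(rng.normal(size=200), n_boot=200, rng=rng)
        assert res.ci_low <= res.ci_high

    def test_width_shrinks_like_root_n(self):
        widths = {}
        g = np.random.default_rng(0)
        for n in (50, 200, 800):
            x = np.random.default_rng(1).normal(size=n)
            res = sim.bootstrap_ci(x, n_boot=2000, rng=g)
            widths[n] = res.ci_high - res.ci_low
        assert widths[50] / widths[200] == pytest.approx(2.0, rel=0.35)
        assert widths[200] / widths[800] == pytest.approx(2.0, rel=0.35)

    def test_too_few_values_rejected(self, rng):
        with pytest.raises(ValueError):
            sim.bootstrap_ci(np.array([1.0]), rng=rng)


class TestRunExperiment:
    def test_grid_cardinality_and_determinism(self, small_community):
        census, traits = small_community
        cfg = sim.ExperimentConfig(n_reps=10, n_boot=20, seed=5)
        a = sim.summaries_to_frame(sim.run_experiment(census, traits, cfg))
        b = sim.summaries_to_frame(sim.run_experiment(census, traits, cfg))
        assert len(a) == 3 * 5 * 2
        pd.testing.assert_frame_equal(a, b)  # bit-for-bit

    def test_control_mean_near_zero_on_null_community(self, null_community):
        census, traits = null_community
        cfg = sim.ExperimentConfig(
            scenarios=("control",), intensities=(1.0,), options=("wsg_swap",),
            n_reps=100, n_boot=200, seed=2,
        )
        (s,) = sim.run_experiment(census, traits, cfg)
        assert abs(s.mean_dagc_pct) < 3 * max(s.se_boot, 1e-12)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ValueError, match="n_rep "):
            sim.ExperimentConfig.from_dict({"n_rep ": 3})

    def test_rerun_bootstrap_mode_agrees_with_resampling(self, toy):
        census, traits = toy
        cfg = sim.ExperimentConfig(
            scenarios=("all_lbf",), intensities=(1.0,), options=("wsg_swap",),
            n_reps=20, n_boot=10, seed=1, bootstrap_mode="rerun",
        )
        (s,) = sim.run_experiment(census, traits, cfg)
        # the toy run is deterministic, so every rerun mean coincides
        assert s.mean_dagc_pct == pytest.approx(-100 / 7, rel=1e-9)
        assert s.ci_low == pytest.approx(s.ci_high)
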