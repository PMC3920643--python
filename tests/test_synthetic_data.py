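import numpy as np
import pandas as pd
import pytest

from commphylo import (
    mean_family_age,
    realized_cold_tolerances,
    shared_path_matrix,
    write_newick,
)
from commphylo.errors import ValidationError
from commphylo.synthetic_data import (
    ScenarioConfig,
    assemble_communities,
    assign_families,
    build_raster,
    generate_ranges,
    generate_scenario,
    simulate_trait,
    simulate_tree,
)


class TestSimulateTree:
    def test_four_tips_shape_and_ultrametry(self):
        t = simulate_tree(4, birth_rate=0.1, seed=0)
        assert t.n_tips == 4
        internal = [n for n in t.iter_preorder() if not n.is_tip]
        assert len(internal) == 3
        assert t.is_ultrametric()

    def test_same_seed_same_newick(self):
        a = write_newick(simulate_tree(30, birth_rate=0.05, seed=123))
        b = write_newick(simulate_tree(30, birth_rate=0.05, seed=123))
        assert a == b

    def test_lineage_count_grows_exponentially(self):
        """E[N(u)] = 2 exp(b u) counted from the root split (Yule growth law)."""
        b, u = 0.1, 10.0
        counts = []
        for s in range(500):
            t = simulate_tree(200, birth_rate=b, seed=s)
            T = t.root_age
            crossing = sum(
                1
                for n in t.iter_preorder()
                if n.parent is not None and n.age < T - u <= n.parent.age
            )
            counts.append(crossing)
        expected = 2 * np.exp(b * u)
        assert np.mean(counts) == pytest.approx(expected, rel=0.2)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValidationError):
            simulate_tree(3, birth_rate=0.1, seed=0)


class TestAssignFamilies:
    def test_cut_near_root_gives_root_adjacent_clades(self):
        t = simulate_tree(30, birth_rate=0.1, seed=4)
        eps = 1e-6
        fam = assign_families(t, t.root_age - eps)
        n_root_clades = len(t.root.children)
        assert len(fam.family_age) == n_root_clades

    def test_cut_near_tips_every_species_own_family(self):
        t = simulate_tree(20, birth_rate=0.1, seed=5)
        youngest = min(n.age for n in t.iter_preorder() if not n.is_tip)
        eps = youngest / 2
        fam = assign_families(t, eps)
        assert len(fam.family_age) == 20
        assert all(a == pytest.approx(eps) for a in fam.family_age.values())

    def test_families_partition_tips(self):
        t = simulate_tree(80, birth_rate=0.05, seed=6)
        fam = assign_families(t, 40.0)
        assert sorted(fam.species_to_family) == sorted(t.tips)
        # ages positive and bounded by the cut for non-monotypic families
        for f, a in fam.family_age.items():
            assert 0 < a <= 40.0 + 1e-9


class TestSimulateTrait:
    def test_ou_stationary_tip_variance(self):
        t = simulate_tree(16, birth_rate=0.2, seed=7)
        alpha = 20.0 / t.root_age  # alpha * depth >> 1
        sigma2 = 2.0
        rng = np.random.default_rng(8)
        vals = np.array(
            [
                simulate_trait(t, "OU", {"alpha": alpha, "sigma2": sigma2, "theta": 0.0},
                               seed=rng).to_numpy()
                for _ in range(2000)
            ]
        )
        stat_var = sigma2 / (2 * alpha)
        assert np.mean(vals.var(axis=0)) == pytest.approx(stat_var, rel=0.10)

    def test_small_alpha_limit_matches_bm_variance(self):
        t = simulate_tree(12, birth_rate=0.2, seed=9)
        sigma2 = 1.0
        rng = np.random.default_rng(10)
        vals = np.array(
            [
                simulate_trait(
                    t, "OU", {"alpha": 1e-5, "sigma2": sigma2, "theta": 0.0}, seed=rng
                ).to_numpy()
                for _ in range(1500)
            ]
        )
        depths = t.tip_depths()
        ratio = vals.var(axis=0) / (sigma2 * depths)
        assert abs(ratio.mean() - 1.0) < 0.10

    def test_trend_ou_tracks_declining_optimum(self):
        t = simulate_tree(40, birth_rate=0.1, seed=11)
        rng = np.random.default_rng(12)
        vals = np.array(
            [
                simulate_trait(
                    t,
                    "trend-OU",
                    {"alpha": 0.5, "sigma2": 0.1, "theta_root": 0.0, "theta_tip": -30.0},
                    seed=rng,
                ).to_numpy()
                for _ in range(200)
            ]
        )
        # strong tracking: tip means near the present-day optimum (within the lag b/alpha)
        lag = 30.0 / t.root_age / 0.5
        assert np.mean(vals) == pytest.approx(-30.0 + lag, abs=1.0)

    def test_family_trend_ou_couples_age_and_tolerance(self):
        t = simulate_tree(150, birth_rate=0.05, seed=13)
        cut = t.root_age * 0.6
        fam = assign_families(t, cut)
        x = simulate_trait(
            t,
            "family-trend-OU",
            {"alpha": 0.1, "sigma2": 2.0, "theta_root": -2.0, "theta_tip": -38.0,
             "cut_age": cut},
            seed=14,
        )
        fmean = x.groupby(pd.Series(fam.species_to_family)).mean()
        fage = pd.Series(fam.family_age)[fmean.index]
        assert np.corrcoef(fage, fmean)[0, 1] > 0.3

    def test_invalid_alpha_rejected(self, six_tip_tree):
        with pytest.raises(ValidationError):
            simulate_trait(six_tip_tree, "OU", {"alpha": 0.0, "sigma2": 1.0, "theta": 0.0})


class TestRaster:
    def test_zero_noise_exact_linear_field(self):
        r = build_raster(dims=(12, 10), gradient=-1.5, noise_sd=0.0, seed=0, base=40.0)
        nrows = 12
        for row in (0, 5, 11):
            lat = r.yll + (nrows - row - 0.5) * r.cellsize
            np.testing.assert_allclose(r.grid[row], 40.0 - 1.5 * lat)

    def test_row_means_decrease_northward(self):
        r = build_raster(dims=(30, 30), gradient=-1.6, noise_sd=1.0, seed=1)
        means = r.grid.mean(axis=1)
        # row 0 is the north: coldest
        assert means[0] < means[-1]
        slope = np.polyfit(np.arange(30), means, 1)[0]
        assert slope == pytest.approx(1.6 * r.cellsize, rel=0.15)

    def test_seeded_reproducibility(self):
        a = build_raster(seed=5)
        b = build_raster(seed=5)
        np.testing.assert_array_equal(a.grid, b.grid)


class TestRanges:
    def test_tolerance_below_minimum_gets_full_grid(self):
        r = build_raster(dims=(10, 10), noise_sd=0.0, seed=0)
        rm = generate_ranges(pd.Series({"sp": -100.0}), r, breadth=None)
        assert len(rm["sp"]) == 100

    def test_tolerance_above_maximum_excluded(self):
        r = build_raster(dims=(10, 10), noise_sd=0.0, seed=0)
        rm = generate_ranges(pd.Series({"sp": 100.0}), r)
        assert "sp" not in rm

    def test_round_trip_realized_at_least_input(self):
        # tolerances chosen inside the raster's value span (a precondition)
        r = build_raster(dims=(40, 40), noise_sd=0.0, seed=0)
        tols = pd.Series({f"s{i}": v for i, v in enumerate(np.linspace(-30, 0, 8))})
        rm = generate_ranges(tols, r)
        realized = realized_cold_tolerances(rm, r)
        step = abs(-1.6) * r.cellsize  # one latitudinal gradient step
        for sp in rm:
            assert realized[sp] >= tols[sp] - 1e-9
            assert realized[sp] <= tols[sp] + step + 1e-9


class TestAssembleCommunities:
    def test_plots_only_contain_available_species(self, scenario_small):
        sc = scenario_small
        for pid in sc.communities.plots.index[:30]:
            cell = (
                int(sc.communities.plots.loc[pid, "cell_row"]),
                int(sc.communities.plots.loc[pid, "cell_col"]),
            )
            for sp in sc.communities.species_at(pid):
                assert cell in sc.ranges[sp]

    def test_minimum_richness_two(self, scenario_small):
        assert (scenario_small.communities.richness() >= 2).all()

    def test_single_species_pool_yields_no_plot(self):
        r = build_raster(dims=(10, 10), noise_sd=0.0, seed=0)
        rm = {"only": {(0, 0)}}
        with pytest.raises(ValidationError):
            assemble_communities(rm, r, n_plots=5, seed=0)


class TestScenario:
    def test_fully_reproducible_under_one_seed(self):
        cfg = ScenarioConfig(
            n_species=40, n_plots=60, raster_dims=(12, 12), family_cut_age=25.0, seed=3
        )
        a = generate_scenario(cfg)
        b = generate_scenario(cfg)
        assert write_newick(a.tree) == write_newick(b.tree)
        pd.testing.assert_frame_equal(a.traits, b.traits)
        np.testing.assert_array_equal(a.raster.grid, b.raster.grid)
        pd.testing.assert_frame_equal(a.communities.incidence, b.communities.incidence)

    def test_emergent_mfa_temperature_gradient(self, scenario_small):
        sc = scenario_small
        mfa = mean_family_age(sc.communities, sc.families)
        temp = np.array(
            [
                sc.raster.grid[int(r), int(c)]
                for r, c in zip(sc.communities.plots["cell_row"],
                                sc.communities.plots["cell_col"])
            ]
        )
        assert np.corrcoef(mfa.to_numpy(), temp)[0, 1] > 0.3

    def test_tolerance_window_drives_occupancy(self, scenario_small):
        # every species' realized tolerance sits at or above its simulated one
        from commphylo import realized_cold_tolerances

        sc = scenario_small
        realized = realized_cold_tolerances(sc.ranges, sc.raster)
        simulated = sc.traits["cold_tolerance"][realized.index]
        assert (realized >= simulated - 1e-9).all()
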