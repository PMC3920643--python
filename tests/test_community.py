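import numpy as np
import pandas as pd
import pytest

from commphylo import (
    CommunityTable,
    FamilyAgeMap,
    RangeMap,
    TemperatureRaster,
    community_trait_mean,
    filter_plots,
    mean_family_age,
    realized_cold_tolerance,
    realized_cold_tolerances,
)
from commphylo.errors import CommPhyloError, ValidationError


def make_table(incidence: dict, natural=None) -> CommunityTable:
    inc = pd.DataFrame(incidence).T.fillna(0).astype(int)
    meta = pd.DataFrame(
        {"lon": 0.0, "lat": 0.0, "natural": True if natural is None else natural},
        index=inc.index,
    )
    return CommunityTable(incidence=inc, plots=meta)


@pytest.fixture
def small_table():
    return make_table(
        {
            "p1": {"sp1": 1, "sp2": 1},
            "p2": {"sp1": 1},
            "p3": {"sp2": 1, "sp3": 1, "sp4": 1},
        },
        natural=[True, True, False],
    )


class TestFilterPlots:
    def test_single_species_plot_removed(self, small_table):
        out = filter_plots(small_table)
        assert "p2" not in out.plots.index

    def test_two_species_natural_plot_retained(self, small_table):
        out = filter_plots(small_table, natural_only=True)
        assert list(out.plots.index) == ["p1"]

    def test_random_fixture_matches_hand_count(self, rng):
        n_plots, n_sp = 100, 12
        inc = pd.DataFrame(
            (rng.random((n_plots, n_sp)) < 0.15).astype(int),
            index=[f"p{i}" for i in range(n_plots)],
            columns=[f"sp{j}" for j in range(n_sp)],
        )
        meta = pd.DataFrame({"lon": 0.0, "lat": 0.0}, index=inc.index)
        table = CommunityTable(inc, meta)
        out = filter_plots(table, min_species=2)
        expected = sum(1 for i in range(n_plots) if inc.iloc[i].sum() >= 2)
        assert len(out.plots) == expected

    def test_everything_filtered_raises(self):
        t = make_table({"p1": {"sp1": 1}})
        with pytest.raises(CommPhyloError, match="min_species"):
            filter_plots(t)


class TestMFA:
    def test_mean_of_two_family_ages(self):
        t = make_table({"p1": {"sp1": 1, "sp2": 1}})
        ages = FamilyAgeMap({"sp1": "famA", "sp2": "famB"}, {"famA": 104.0, "famB": 56.0})
        assert mean_family_age(t, ages)["p1"] == pytest.approx(80.0)

    def test_single_family_gives_that_age(self):
        t = make_table({"p1": {"sp1": 1, "sp2": 1, "sp3": 1}})
        ages = FamilyAgeMap({f"sp{i}": "famA" for i in (1, 2, 3)}, {"famA": 62.0})
        assert mean_family_age(t, ages)["p1"] == pytest.approx(62.0)

    def test_matches_per_plot_loop_oracle(self, rng):
        species = [f"sp{j}" for j in range(15)]
        fams = {s: f"fam{j % 5}" for j, s in enumerate(species)}
        ages = FamilyAgeMap(fams, {f"fam{k}": 20.0 + 15 * k for k in range(5)})
        inc = pd.DataFrame(0, index=[f"p{i}" for i in range(20)], columns=species)
        for i in range(20):
            chosen = rng.choice(15, size=rng.integers(2, 8), replace=False)
            inc.iloc[i, chosen] = 1
        meta = pd.DataFrame({"lon": 0.0, "lat": 0.0}, index=inc.index)
        table = CommunityTable(inc, meta)
        mfa = mean_family_age(table, ages)
        for pid in inc.index:
            present = [s for s in species if inc.loc[pid, s]]
            oracle = np.mean([ages.age_of(s) for s in present])
            assert mfa[pid] == pytest.approx(oracle, abs=1e-10)

    def test_unmapped_species_listed(self):
        t = make_table({"p1": {"sp1": 1, "spX": 1}})
        ages = FamilyAgeMap({"sp1": "famA"}, {"famA": 10.0})
        with pytest.raises(ValidationError, match="spX"):
            mean_family_age(t, ages)

    def test_bounded_by_family_ages_present(self, scenario_small):
        from commphylo import mean_family_age as mfa_fn

        sc = scenario_small
        mfa = mfa_fn(sc.communities, sc.families)
        for pid in sc.communities.plots.index[:25]:
            ages = [sc.families.age_of(s) for s in sc.communities.species_at(pid)]
            assert min(ages) - 1e-9 <= mfa[pid] <= max(ages) + 1e-9


def toy_raster():
    grid = np.array([[-20.0, -5.0], [3.0, -9999.0]])
    return TemperatureRaster(grid=grid, xll=0.0, yll=0.0, cellsize=1.0)


class TestColdTolerance:
    def test_minimum_over_range(self):
        r = TemperatureRaster(
            grid=np.array([[-5.0, -20.0], [3.0, 1.0]]), xll=0, yll=0, cellsize=1.0
        )
        assert realized_cold_tolerance({(0, 0), (0, 1), (1, 0)}, r) == -20.0

    def test_single_cell_range(self):
        assert realized_cold_tolerance({(1, 0)}, toy_raster()) == 3.0

    def test_nodata_only_overlap_rejected(self):
        with pytest.raises(ValidationError):
            realized_cold_tolerance({(1, 1)}, toy_raster())

    def test_bounded_below_by_raster_minimum_and_monotone(self, scenario_small):
        sc = scenario_small
        tol = realized_cold_tolerances(sc.ranges, sc.raster)
        gmin = sc.raster.grid[~sc.raster.mask].min()
        assert (tol >= gmin).all()
        # enlarging a range can only keep or lower the realized tolerance
        sp = tol.index[0]
        bigger = set(sc.ranges[sp]) | {(0, 0)}
        assert realized_cold_tolerance(bigger, sc.raster) <= tol[sp]


class TestCommunityTraitMean:
    def test_mean_of_two_tolerances(self):
        t = make_table({"p1": {"sp1": 1, "sp2": 1}})
        out = community_trait_mean(t, {"sp1": -10.0, "sp2": -30.0})
        assert out["p1"] == pytest.approx(-20.0)

    def test_dispersal_rank_coding(self):
        from commphylo.community import DISPERSAL_RANK

        t = make_table({"p1": {"sp1": 1, "sp2": 1}})
        coded = {"sp1": DISPERSAL_RANK["unassisted"], "sp2": DISPERSAL_RANK["wind"]}
        assert community_trait_mean(t, coded)["p1"] == pytest.approx(2.0)

    def test_missing_species_excluded_from_mean_only(self):
        t = make_table({"p1": {"sp1": 1, "sp2": 1, "sp3": 1}})
        out = community_trait_mean(t, {"sp1": 4.0, "sp2": 8.0, "sp3": np.nan})
        assert out["p1"] == pytest.approx(6.0)

    def test_matches_loop_oracle(self, rng):
        species = [f"sp{j}" for j in range(10)]
        traits = pd.Series(rng.normal(size=10), index=species)
        inc = pd.DataFrame(
            (rng.random((20, 10)) < 0.4).astype(int),
            index=[f"p{i}" for i in range(20)],
            columns=species,
        )
        inc.iloc[:, 0] = 1  # no empty plots
        meta = pd.DataFrame({"lon": 0.0, "lat": 0.0}, index=inc.index)
        out = community_trait_mean(CommunityTable(inc, meta), traits)
        for pid in inc.index:
            present = [s for s in species if inc.loc[pid, s]]
            assert out[pid] == pytest.approx(traits[present].mean(), abs=1e-10)


class TestRasterIO:
    def test_ascii_round_trip(self, tmp_path, scenario_small):
        r = scenario_small.raster
        p = tmp_path / "grid.asc"
        r.write_ascii(p)
        r2 = TemperatureRaster.read_ascii(p)
        np.testing.assert_allclose(r2.grid, r.grid, rtol=1e-5)
        assert r2.cellsize == pytest.approx(r.cellsize)

    def test_cell_addressing_row_major_from_northwest(self):
        r = TemperatureRaster(grid=np.arange(12.0).reshape(3, 4), xll=10.0, yll=40.0,
                              cellsize=1.0)
        assert r.cell_of(10.5, 42.5) == (0, 0)  # NW corner
        assert r.cell_of(13.5, 40.5) == (2, 3)  # SE corner
        lon, lat = r.cell_center(0, 0)
        assert (lon, lat) == (10.5, 42.5)
        with pytest.raises(ValidationError):
            r.cell_of(9.0, 41.0)

    def test_range_map_frame_round_trip(self, scenario_small):
        rm = scenario_small.ranges
        rm2 = RangeMap.from_frame(rm.to_frame())
        assert rm2 == rm
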