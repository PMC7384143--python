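import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from leafprod.gridding import GridSpec
from leafprod.synthetic import (SyntheticScenario, GRFSpec, simulate_grf,
                                make_climate_fields, make_species_pool,
                                make_ranges, make_productivity,
                                make_phylogeny, clades_from_tree,
                                occurrences_from_presence, generate_region)
from leafprod.transfer import fit_transfer, inverse_logistic


def morans_i_lag1(values: np.ndarray, nx: int, ny: int) -> float:
    """Rook-neighbour Moran's I on a regular grid (independent check)."""
    z = values.reshape(ny, nx) - values.mean()
    num = (z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum()
    w = 2 * ((nx - 1) * ny + (ny - 1) * nx) / 2
    return (values.size / w) * num / (z**2).sum()


class TestScenario:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SyntheticScenario(signal_weight=1.5)
        with pytest.raises(ValueError):
            SyntheticScenario(birth_rate=0.1, death_rate=0.2)
        with pytest.raises(ValueError):
            GRFSpec(0.0, -1.0, 100.0)

    def test_json_round_trip(self):
        sc = SyntheticScenario(nx=5, ny=4, n_species=10, seed=7)
        clone = SyntheticScenario.from_json(sc.to_json())
        assert clone == sc


class TestClimateFields:
    def test_seeded_determinism(self, small_scenario):
        a = make_climate_fields(small_scenario)
        b = make_climate_fields(small_scenario)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_range_kills_autocorrelation(self):
        g = GRFSpec(0.0, 1.0, 0.0)
        coords = GridSpec(40, 40, 50).centres()[["x", "y"]].to_numpy()
        rng = np.random.default_rng(1)
        iis = [morans_i_lag1(simulate_grf(coords, g, rng, {}), 40, 40)
               for _ in range(10)]
        assert abs(np.mean(iis)) < 0.05

    def test_positive_range_creates_autocorrelation(self):
        g = GRFSpec(0.0, 1.0, 250.0)
        coords = GridSpec(25, 25, 50).centres()[["x", "y"]].to_numpy()
        rng = np.random.default_rng(2)
        i1 = morans_i_lag1(simulate_grf(coords, g, rng, {}), 25, 25)
        assert i1 > 0.3

    def test_zero_sill_gives_constant_mean(self):
        coords = GridSpec(5, 5, 50).centres()[["x", "y"]].to_numpy()
        out = simulate_grf(coords, GRFSpec(3.0, 0.0, 100.0),
                           np.random.default_rng(0), {})
        np.testing.assert_array_equal(out, 3.0)

    def test_aet_is_monotone_in_supply_and_demand(self, small_scenario):
        cells = make_climate_fields(small_scenario)
        # AET = min(MAP, PET): never exceeds MAP, correlates with both
        assert (cells["AET"] <= cells["MAP"] + 1e-9).all()
        assert pearsonr(cells["AET"], cells["MAP"]).statistic > 0.3
        assert pearsonr(cells["AET"], cells["MAT"]).statistic > 0.3


class TestSpeciesPool:
    def test_decoupled_limit(self):
        sc = SyntheticScenario(n_species=1000, niche_coupling=0.0, seed=3)
        pool = make_species_pool(sc)
        med = (pool["length_min"] + pool["length_max"]) / 2
        rho = pearsonr(np.log(med), pool["niche_optimum"]).statistic
        assert abs(rho) < 0.1

    def test_default_coupling_is_positive(self):
        pool = make_species_pool(SyntheticScenario(n_species=1000, seed=4))
        med = (pool["length_min"] + pool["length_max"]) / 2
        rho = spearmanr(med, pool["niche_optimum"]).statistic
        assert rho > 0.5

    def test_single_species_valid_ranges(self):
        pool = make_species_pool(SyntheticScenario(n_species=1, seed=5))
        r = pool.iloc[0]
        assert 0 < r["length_min"] <= r["length_max"]
        assert 0 < r["width_min"] <= r["width_max"]


class TestRanges:
    def test_same_seed_identical(self, small_scenario):
        clim = make_climate_fields(small_scenario)
        pool = make_species_pool(small_scenario)
        a = make_ranges(pool, clim, small_scenario)
        b = make_ranges(pool, clim, small_scenario)
        pd.testing.assert_frame_equal(a, b)

    def test_every_species_occupies_a_cell(self, region):
        assert region["presence"].any(axis=0).all()

    def test_saturating_breadth_fills_grid(self, small_scenario):
        sc = dataclasses.replace(small_scenario, niche_breadth=1e9)
        clim = make_climate_fields(sc)
        pool = make_species_pool(sc)
        assert make_ranges(pool, clim, sc).all().all()

    def test_community_mean_tracks_aet(self, default_region):
        from leafprod.gridding import filter_richness
        cells, _ = filter_richness(default_region["cells"])
        rho = spearmanr(cells["AET"], cells["mean_length"]).statistic
        assert rho > 0.7

    def test_occurrence_records_round_trip(self, small_scenario, region):
        from leafprod.gridding import rasterize_occurrences
        occ = occurrences_from_presence(region["presence"].iloc[:, :20],
                                        small_scenario.grid)
        back = rasterize_occurrences(occ, small_scenario.grid)
        orig = region["presence"].iloc[:, :20]
        orig = orig.loc[orig.any(axis=1), orig.any(axis=0)]
        pd.testing.assert_frame_equal(
            back.sort_index(axis=1), orig.sort_index(axis=1),
            check_names=False)


class TestProductivity:
    def test_printed_formula_value(self, region, small_scenario):
        sc = dataclasses.replace(small_scenario, noise_frac=0.0)
        lp = sc.transfer[("GPP", "length")]
        assert inverse_logistic(5.0, *lp.as_tuple())[()] == pytest.approx(
            596.0, abs=0.1)

    def test_zero_noise_round_trip_recovers_parameters(self, small_scenario):
        sc = dataclasses.replace(small_scenario, noise_frac=0.0)
        reg = generate_region(sc)
        m = fit_transfer(reg["cells"]["mean_length"], reg["cells"]["GPP"])
        lp = sc.transfer[("GPP", "length")]
        assert m.params["K"] == pytest.approx(lp.K, rel=1e-3)
        assert m.params["alpha"] == pytest.approx(lp.alpha, rel=1e-3)
        assert m.params["r"] == pytest.approx(lp.r, rel=1e-3)

    def test_trait_above_K_raises_naming_cells(self, small_scenario):
        clim = make_climate_fields(small_scenario)
        cells = clim.assign(mean_length=20.0)
        with pytest.raises(ValueError, match="K"):
            make_productivity(cells, small_scenario)

    def test_gpp_bounds_npp(self, region):
        c = region["cells"]
        assert (c["GPP"] >= c["NPP"]).all()
        assert (c["NPP"] >= 0).all()

    def test_year_stack_present_and_centred(self, small_scenario):
        reg = generate_region(small_scenario, with_years=True)
        ycols = [c for c in reg["cells"].columns if c.startswith("GPP_y")]
        assert len(ycols) == small_scenario.n_years
        yearly = reg["cells"][ycols].mean(axis=1)
        assert pearsonr(yearly, reg["cells"]["GPP"]).statistic > 0.95


class TestPhylogenyGenerator:
    def test_same_seed_identical_newick(self):
        sc = SyntheticScenario()
        a, _ = make_phylogeny(sc, seed=9, n_tips=20)
        b, _ = make_phylogeny(sc, seed=9, n_tips=20)
        assert a.tree.as_string(schema="newick") == b.tree.as_string(schema="newick")

    def test_tree_is_ultrametric(self):
        ph, _ = make_phylogeny(SyntheticScenario(), seed=10, n_tips=30)
        assert ph.ultrametric

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            make_phylogeny(SyntheticScenario(), n_tips=2)

    def test_clade_cut_partitions_all_tips(self):
        ph, _ = make_phylogeny(SyntheticScenario(), seed=13, n_tips=40)
        depth = float(np.max(np.diag(ph.vcv)))
        clades, ages = clades_from_tree(ph, depth / 2)
        assert set(clades.index) == set(ph.taxa)
        assert (ages > 0).all()
        # stem ages straddle the cut
        assert (ages.loc[clades.unique()] >= depth / 2 - 1e-9).any()


class TestRegionDeterminism:
    def test_full_region_bitwise_reproducible(self, small_scenario, region):
        again = generate_region(small_scenario)
        pd.testing.assert_frame_equal(region["cells"], again["cells"])

    def test_different_seed_differs(self, small_scenario, region):
        other = generate_region(small_scenario, seed=99)
        assert not region["cells"]["GPP"].equals(other["cells"]["GPP"])
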