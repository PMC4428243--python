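"""Synthetic-data generator: lattice geometry, pigment fields, mortality."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from cyanorisk.geo_synth import (SyntheticScenario, forward_reflectance,
                                 make_county_grid, make_covariates,
                                 make_pigment_field, sample_icar,
                                 simulate_mortality)
from cyanorisk.regions import CountyMap
from cyanorisk.retrieval import OpticalConstants, retrieve_pigments


class TestCountyGrid:
    def test_single_county_has_no_neighbors(self):
        cm = make_county_grid(1, 1, 10.0)
        assert len(cm) == 1
        assert cm.neighbors[0] == []
        assert cm.areas[0] == pytest.approx(100.0)

    def test_2x2_corner_touching_counts_as_adjacency(self):
        cm = make_county_grid(2, 2, 10.0)
        assert all(len(nb) == 3 for nb in cm.neighbors)

    def test_3x3_adjacency_matches_brute_force_polygon_pairs(self):
        cm = make_county_grid(3, 3, 10.0)
        # oracle: enumerate every polygon pair and test boundary contact
        n = len(cm)
        expected = [set() for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i != j and cm.polygons[i].intersects(cm.polygons[j]):
                    expected[i].add(j)
        assert [set(nb) for nb in cm.neighbors] == expected
        assert len(cm.neighbors[4]) == 8  # center county

    def test_rejects_nonpositive_dimensions(self):
        with pytest.raises(ValueError):
            make_county_grid(0, 3)
        with pytest.raises(ValueError):
            make_county_grid(2, 2, cell_size=0)


class TestPigmentField:
    def test_zero_prevalence_gives_zero_coverage(self, grid3):
        scen = SyntheticScenario(grid_nx=3, grid_ny=3, pixels_per_county=10,
                                 water_fraction=0.5, bloom_prevalence=0.0, seed=1)
        _, cov = make_pigment_field(grid3, scen)
        assert np.all(cov == 0.0)

    def test_full_prevalence_full_water_gives_full_coverage(self, grid3):
        scen = SyntheticScenario(grid_nx=3, grid_ny=3, pixels_per_county=10,
                                 water_fraction=1.0, bloom_prevalence=1.0, seed=1)
        _, cov = make_pigment_field(grid3, scen)
        assert np.allclose(cov, 100.0)

    def test_quarter_prevalence_within_one_pixel(self, grid3):
        scen = SyntheticScenario(grid_nx=3, grid_ny=3, pixels_per_county=20,
                                 water_fraction=1.0, bloom_prevalence=0.25, seed=1)
        raster, cov = make_pigment_field(grid3, scen)
        one_pixel_pct = 100.0 / 20 ** 2
        assert np.all(np.abs(cov - 25.0) <= one_pixel_pct)
        # ground truth agrees with directly counting mask pixels
        n_bloom = (raster.pc >= 4.0) & raster.water_mask
        assert n_bloom.sum() == int(round(cov.sum() / one_pixel_pct))

    def test_determinism_bit_identical(self, grid3, small_scenario):
        a, cov_a = make_pigment_field(grid3, small_scenario)
        b, cov_b = make_pigment_field(grid3, small_scenario)
        assert np.array_equal(a.pc, b.pc)
        assert np.array_equal(a.chl, b.chl)
        assert np.array_equal(a.water_mask, b.water_mask)
        assert np.array_equal(cov_a, cov_b)


class TestForwardReflectance:
    def test_zero_pigment_band_ratio_limit(self, grid3):
        scen = SyntheticScenario(grid_nx=3, grid_ny=3, pixels_per_county=5,
                                 water_fraction=1.0, bloom_prevalence=0.0, seed=1)
        raster, _ = make_pigment_field(grid3, scen)
        raster.pc[:] = 0.0
        raster.chl[:] = 0.0
        c = OpticalConstants()
        b_b = 0.3
        scene = forward_reflectance(raster, b_b=b_b, consts=c)
        expected_ratio = (c.a_w709 + b_b) / (c.a_w620 + b_b)
        ratio = scene.B620[raster.water_mask] / scene.B705[raster.water_mask]
        assert np.allclose(1.0 / ratio, 1.0 / expected_ratio)

    def test_doubling_pc_strictly_decreases_B620(self, grid3, small_scenario):
        raster, _ = make_pigment_field(grid3, small_scenario)
        w = raster.water_mask & (raster.pc > 0)
        scene1 = forward_reflectance(raster, b_b=0.2)
        raster2 = type(raster)(pc=raster.pc * 2, chl=raster.chl,
                               qa_mask=raster.qa_mask,
                               water_mask=raster.water_mask, grid=raster.grid)
        scene2 = forward_reflectance(raster2, b_b=0.2)
        assert np.all(scene2.B620[w] < scene1.B620[w])

    def test_round_trip_recovers_pigments(self, grid3, small_scenario):
        raster, _ = make_pigment_field(grid3, small_scenario)
        for b_b in (0.05, 0.2, 1.0):
            scene = forward_reflectance(raster, b_b=b_b)
            rec = retrieve_pigments(scene)
            w = raster.water_mask
            assert np.allclose(rec.pc[w], raster.pc[w], rtol=1e-9, atol=1e-12)
            assert np.allclose(rec.chl[w], raster.chl[w], rtol=1e-9, atol=1e-12)

    def test_rejects_nonpositive_backscatter(self, grid3, small_scenario):
        raster, _ = make_pigment_field(grid3, small_scenario)
        with pytest.raises(ValueError):
            forward_reflectance(raster, b_b=0.0)


class TestSimulateMortality:
    def test_null_model_mean_matches_expected(self):
        """With no covariate effect and no random effects, E[Y_i] = E_i."""
        cm = make_county_grid(2, 2, 10.0)
        ratios = []
        for s in range(2000):
            scen = SyntheticScenario(grid_nx=2, grid_ny=2, true_beta=(0.0,),
                                     true_alpha=0.0, sigma_e=0.0, sigma_phi=0.0,
                                     n_strata=4, mean_expected_deaths=50.0,
                                     seed=s)
            sim = simulate_mortality(cm, np.zeros((4, 1)), scen)
            ratios.append(sim.y / sim.expected)
        ratios = np.concatenate(ratios)
        se = ratios.std(ddof=1) / np.sqrt(ratios.size)
        assert abs(ratios.mean() - 1.0) < 3 * se

    def test_determinism_identical_tables(self, grid3):
        scen = SyntheticScenario(grid_nx=3, grid_ny=3, seed=5)
        cov = np.zeros((9, 3))
        a = simulate_mortality(grid3, cov, scen)
        b = simulate_mortality(grid3, cov, scen)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert np.array_equal(a.phi, b.phi)

    def test_large_r_approaches_poisson(self):
        """NB with huge dispersion r collapses to Poisson: Var((Y-E)/sqrt(E)) -> 1."""
        cm = make_county_grid(1, 1, 10.0)
        z = []
        for s in range(4000):
            scen = SyntheticScenario(grid_nx=1, grid_ny=1, true_beta=(0.0,),
                                     sigma_e=0.0, sigma_phi=0.0, true_r=1e9,
                                     n_strata=4, mean_expected_deaths=100.0,
                                     seed=s)
            sim = simulate_mortality(cm, np.zeros((1, 1)), scen)
            z.append((sim.y[0] - sim.expected[0]) / np.sqrt(sim.expected[0]))
        z = np.asarray(z)
        assert abs(z.var(ddof=1) - 1.0) < 0.08  # ~3x the MC sd of a variance

    def test_deaths_table_consistent_with_totals(self, grid3, small_scenario):
        cov = make_covariates(grid3, small_scenario)
        sim = simulate_mortality(grid3, cov, small_scenario)
        totals = sim.table.groupby("county_id", sort=True)["deaths"].sum()
        assert np.allclose(totals.to_numpy(), sim.y)
        assert (sim.table["deaths"] <= sim.table["population"]).all()

    def test_covariate_row_mismatch_rejected(self, grid3, small_scenario):
        with pytest.raises(ValueError):
            simulate_mortality(grid3, np.zeros((4, 3)), small_scenario)


class TestIcar:
    def test_sum_to_zero_per_component(self, rng):
        # two disconnected 2x2 blocks, far apart
        polys, ids = [], []
        for block, x0 in enumerate((0.0, 1000.0)):
            for iy in range(2):
                for ix in range(2):
                    ids.append(f"B{block}{iy}{ix}")
                    polys.append(box(x0 + ix * 10, iy * 10,
                                     x0 + (ix + 1) * 10, (iy + 1) * 10))
        cm = CountyMap(ids=ids, polygons=polys)
        comps = cm.connected_components()
        assert len(comps) == 2
        phi = sample_icar(cm, sigma_phi=0.7, rng=rng)
        for comp in comps:
            assert abs(phi[comp].sum()) < 1e-10

    def test_zero_sigma_gives_zero_field(self, grid3, rng):
        assert np.all(sample_icar(grid3, 0.0, rng) == 0)

    def test_conditional_variance_scaling(self, rng):
        """Marginal ICAR variance grows with sigma_phi^2 (sanity on the scale)."""
        cm = make_county_grid(6, 6, 10.0)
        draws1 = np.array([sample_icar(cm, 0.5, np.random.default_rng(s))
                           for s in range(200)])
        draws2 = np.array([sample_icar(cm, 1.0, np.random.default_rng(s))
                           for s in range(200)])
        assert np.allclose(draws2, 2.0 * draws1)
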