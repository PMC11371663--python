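import numpy as np
import pytest
from scipy import stats

import nichelegacy as nl


class TestLandscapeGeneration:
    def test_same_seed_reproduces_bit_identical_grids(self):
        spec = nl.LandscapeSpec(seed=11)
        a = nl.generate_climate_landscape(spec)
        b = nl.generate_climate_landscape(nl.LandscapeSpec(seed=11))
        np.testing.assert_array_equal(a.grid.values, b.grid.values)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_rank_one_construction_gives_identical_variables(self):
        spec = nl.LandscapeSpec(n_vars=4, latent_dim=1, noise_sd=0.0,
                                mixing=np.ones((4, 1)), seed=0)
        land = nl.generate_climate_landscape(spec)
        v = land.grid.values
        # every variable is the same field up to its per-variable affine units
        base = (v[:, :, 0] - v[:, :, 0].mean()) / v[:, :, 0].std()
        for k in range(1, 4):
            other = (v[:, :, k] - v[:, :, k].mean()) / v[:, :, k].std()
            np.testing.assert_allclose(other, base, atol=1e-10)

    def test_two_latent_factors_dominate_the_correlation_spectrum(self):
        spec = nl.LandscapeSpec(latent_dim=2, n_vars=19, noise_sd=0.1, seed=1)
        land = nl.generate_climate_landscape(spec)
        flat = land.grid.values.reshape(-1, 19)
        eigvals = np.linalg.eigvalsh(np.corrcoef(flat.T))[::-1]
        assert eigvals[:2].sum() / eigvals.sum() >= 0.95

    def test_degenerate_mixing_rejected(self):
        spec = nl.LandscapeSpec(n_vars=3, latent_dim=2, mixing=np.zeros((3, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            nl.generate_climate_landscape(spec)

    def test_background_fraction_matches_quantile_band(self):
        spec = nl.LandscapeSpec(seed=2, background_band=(0.15, 0.85))
        land = nl.generate_climate_landscape(spec)
        frac = land.mask.mean()
        # band width 0.70, tolerance of one cell column on a 60-wide lattice
        assert frac == pytest.approx(0.70, abs=1 / 60 + 1e-9)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            nl.LandscapeSpec(n_rows=2)
        with pytest.raises(ValueError):
            nl.LandscapeSpec(n_vars=2, latent_dim=3)
        with pytest.raises(ValueError):
            nl.LandscapeSpec(noise_sd=-0.1)


class TestSampleOccurrences:
    def test_deterministic_given_seed(self, landscape):
        niche = nl.NicheSpec(centroid=[0, 0], breadth=0.5, n_records=100, seed=5)
        a = nl.sample_occurrences(landscape, niche)
        b = nl.sample_occurrences(landscape, niche)
        assert a.equals(b)

    def test_point_mass_limit_all_records_in_one_cell(self, landscape, background):
        # centroid exactly at one background cell's latent value, tiny breadth
        r, c = background.rows[100], background.cols[100]
        centroid = landscape.latent[r, c, :]
        niche = nl.NicheSpec(centroid=centroid, breadth=1e-4, n_records=50, seed=0)
        occ = nl.sample_occurrences(landscape, niche)
        from conftest import cell_occurrences
        co = cell_occurrences(occ, landscape, background)
        np.testing.assert_array_equal(co.cells, [[r, c]])

    def test_uniform_limit_matches_gaussian_weights_chi_square(self, landscape):
        # breadth >> landscape span: occupancy frequencies ~ uniform over the
        # background; chi-square goodness of fit across seeds
        rows, cols = np.nonzero(landscape.mask)
        n_bg = len(rows)
        cell_ids = {(r, c): i for i, (r, c) in enumerate(zip(rows, cols))}
        passed = 0
        n_seeds = 5
        for seed in range(n_seeds):
            niche = nl.NicheSpec(centroid=[0, 0], breadth=1e6, n_records=10_000, seed=seed)
            occ = nl.sample_occurrences(landscape, niche)
            counts = np.zeros(n_bg)
            for lon, lat in zip(occ.decimalLongitude, occ.decimalLatitude):
                cell = landscape.grid.cell_of(lon, lat)
                counts[cell_ids[cell]] += 1
            p = stats.chisquare(counts).pvalue
            passed += p > 0.01
        assert passed >= n_seeds - 1

    def test_unreachable_centroid_is_an_explicit_error(self, landscape):
        niche = nl.NicheSpec(centroid=[500, 500], breadth=0.01, n_records=10, seed=0)
        with pytest.raises(ValueError, match="centroid"):
            nl.sample_occurrences(landscape, niche)

    def test_uncertainty_distribution_and_missing_fraction(self, landscape):
        niche = nl.NicheSpec(centroid=[0, 0], breadth=1.0, n_records=5000, seed=1,
                             missing_uncertainty_frac=0.1)
        occ = nl.sample_occurrences(landscape, niche)
        unc = occ.coordinateUncertaintyInMeters
        assert unc.isna().mean() == pytest.approx(0.1, abs=0.02)
        assert np.median(unc.dropna()) == pytest.approx(500, rel=0.1)

    def test_invalid_niche_specs_rejected(self):
        with pytest.raises(ValueError):
            nl.NicheSpec(centroid=[0, 0], breadth=-1.0)
        with pytest.raises(ValueError):
            nl.NicheSpec(centroid=[0, 0], breadth=1.0, n_records=0)


class TestPairScenarios:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="preset"):
            nl.make_pair_scenario("swapped")

    def test_identical_preset_shares_the_niche(self):
        scen = nl.make_pair_scenario("identical", seed=3, n_per_species=50)
        np.testing.assert_array_equal(scen.niche_a.centroid, scen.niche_b.centroid)
        assert scen.niche_a.seed != scen.niche_b.seed

    def test_nested_preset_scales_breadth(self):
        scen = nl.make_pair_scenario("nested", seed=3, breadth=0.4, nested_ratio=2.0,
                                     n_per_species=50)
        assert float(np.asarray(scen.niche_b.breadth)) == pytest.approx(0.8)

    def test_far_shifted_pair_is_nearly_disjoint_downstream(self, landscape, background,
                                                            space, availability):
        from conftest import occupancy_of
        scen = nl.make_pair_scenario("shifted", separation=3.0, n_per_species=400,
                                     seed=9, landscape=landscape)
        ga = occupancy_of(scen.occurrences_a, landscape, background, space, availability)
        gb = occupancy_of(scen.occurrences_b, landscape, background, space, availability)
        assert nl.schoeners_d(ga.z, gb.z) < 0.1

    def test_two_samples_of_one_niche_overlap_like_self(self, landscape, background,
                                                        space, availability):
        # two species with the same niche but different record seeds score a D
        # close to a niche's self-overlap under resampling
        from conftest import occupancy_of
        ds = []
        for seed in range(6):
            scen = nl.make_pair_scenario("identical", n_per_species=500, seed=seed,
                                         landscape=landscape)
            ga = occupancy_of(scen.occurrences_a, landscape, background, space, availability)
            gb = occupancy_of(scen.occurrences_b, landscape, background, space, availability)
            ds.append(nl.schoeners_d(ga.z, gb.z))
        assert np.mean(ds) > 0.75  # high overlap, limited only by sampling noise


class TestLandscapeIo:
    def test_written_rasters_read_back_into_the_same_grid(self, tmp_path):
        land = nl.generate_climate_landscape(nl.LandscapeSpec(n_rows=10, n_cols=12,
                                                              n_vars=3, seed=4))
        paths = nl.synthetic.write_landscape(land, tmp_path)
        mask_path = paths.pop("background_mask")
        grid = nl.read_climate_grid(paths)
        np.testing.assert_allclose(grid.values, land.grid.values, rtol=1e-6, atol=1e-8)
        from nichelegacy.grids import read_ascii_grid
        mask, *_ = read_ascii_grid(mask_path)
        np.testing.assert_array_equal(mask.astype(bool), land.mask)
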