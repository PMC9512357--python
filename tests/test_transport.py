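"""Monte Carlo engine: attenuation, scoring, filtering, HU conversion."""

import numpy as np
import pytest
from scipy import stats

from phspdose.transport import (
    DoseGrid,
    HUCalibration,
    Phantom,
    _transport_batch,
    first_interaction_depths,
    hu_to_density,
    median_filter,
    mu_rho_water,
    scale_dose,
    simulate_dose,
    water_cube_phantom,
)


def parallel_beam(n, rng, width_mm=20.0, energy_mev=2.0, z0=-160.0):
    """Square parallel photon beam travelling +z toward the phantom."""
    pos = np.column_stack([
        rng.uniform(-width_mm / 2, width_mm / 2, n),
        rng.uniform(-width_mm / 2, width_mm / 2, n),
        np.full(n, z0),
    ])
    direction = np.tile([0.0, 0.0, 1.0], (n, 1))
    return pos, direction, np.full(n, energy_mev)


class TestCrossSections:
    def test_water_attenuation_close_to_reference_values(self):
        # standard water mass attenuation (cm^2/g), coherent excluded
        for e, ref in [(0.5, 0.0966), (1.0, 0.0707), (2.0, 0.0494), (6.0, 0.0277)]:
            assert mu_rho_water(e) == pytest.approx(ref, rel=0.02)

    def test_components_sum_to_total(self):
        e = np.linspace(0.06, 6.0, 50)
        total = mu_rho_water(e, "total")
        parts = sum(mu_rho_water(e, c) for c in ("compton", "photoelectric", "pair"))
        np.testing.assert_allclose(total, parts, rtol=1e-12)


class TestFirstInteraction:
    def test_depth_distribution_is_exponential(self):
        """First-interaction depths follow exp(-mu z) with the packaged mu."""
        ph = water_cube_phantom(side_mm=300.0, voxel_mm=2.0, iso_depth_mm=0.0)
        e = 1.0
        depths = first_interaction_depths(e, 200000, ph, seed=4)
        interacted = depths[depths >= 0]
        mu_mm = mu_rho_water(e) * 1.0 * 0.1
        # compare the truncated-exponential mean over (0, 300 mm)
        L = 300.0
        expected_mean = 1 / mu_mm - L * np.exp(-mu_mm * L) / (1 - np.exp(-mu_mm * L))
        assert interacted.mean() == pytest.approx(expected_mean, rel=0.01)
        # survival fraction through the cube
        p_through = np.exp(-mu_mm * L)
        frac = (depths < 0).mean()
        sigma = np.sqrt(p_through * (1 - p_through) / len(depths))
        assert abs(frac - p_through) < 4 * sigma

    def test_halving_density_halves_attenuation(self):
        ph_half = Phantom(density=np.full((20, 20, 150), 0.5),
                          voxel_size_mm=2.0, origin_mm=(-20.0, -20.0, 0.0))
        depths = first_interaction_depths(1.0, 100000, ph_half, seed=8)
        interacted = depths[depths >= 0]
        mu_mm = mu_rho_water(1.0) * 0.5 * 0.1
        L = 300.0
        expected_mean = 1 / mu_mm - L * np.exp(-mu_mm * L) / (1 - np.exp(-mu_mm * L))
        assert interacted.mean() == pytest.approx(expected_mean, rel=0.02)


class TestSimulateDose:
    def test_symmetric_beam_gives_mirror_symmetric_profile(self):
        ph = water_cube_phantom(side_mm=120.0, voxel_mm=4.0, iso_depth_mm=60.0)
        grid, used = simulate_dose(parallel_beam, ph, max_histories=300000, seed=2)
        assert used == 300000
        d = grid.values
        # lateral profile at mid-depth, averaged over the beam column
        prof = d[:, 12:18, 10:20].mean(axis=(1, 2))
        mirrored = prof[::-1]
        sel = prof > 0.05 * prof.max()
        np.testing.assert_allclose(prof[sel], mirrored[sel], rtol=0.25)

    def test_energy_deposited_bounded_by_energy_entering(self):
        ph = water_cube_phantom(side_mm=100.0, voxel_mm=4.0, iso_depth_mm=50.0)
        rng = np.random.default_rng(3)
        pos, direction, energy = parallel_beam(20000, rng, z0=-60.0)
        edep = np.zeros(ph.density.size)
        e_in, e_dep = _transport_batch(
            pos, direction, energy, ph.density.ravel(), edep,
            *ph.origin_mm, ph.voxel_size_mm, *ph.shape, 1.0, 99,
        )
        assert e_in == pytest.approx(energy.sum(), rel=1e-12)
        assert 0 < e_dep <= e_in
        assert edep.sum() == pytest.approx(e_dep, rel=1e-9)

    def test_uncertainty_scales_as_inverse_sqrt_histories(self):
        ph = water_cube_phantom(side_mm=80.0, voxel_mm=4.0, iso_depth_mm=40.0)
        unc = []
        hs = [20000, 80000, 320000]
        for h in hs:
            grid, _ = simulate_dose(parallel_beam, ph, max_histories=h,
                                    batches=10, seed=11)
            hot = grid.values >= 0.5 * grid.values.max()
            unc.append(np.nanmean(grid.uncertainty[hot]))
        slope = np.polyfit(np.log(hs), np.log(unc), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_target_uncertainty_stops_early(self):
        ph = water_cube_phantom(side_mm=80.0, voxel_mm=4.0, iso_depth_mm=40.0)
        grid, used = simulate_dose(parallel_beam, ph, max_histories=2_000_000,
                                   target_uncertainty=0.05, batches=20, seed=1)
        assert used < 2_000_000
        hot = grid.values >= 0.5 * grid.values.max()
        assert np.nanmean(grid.uncertainty[hot]) <= 0.055

    def test_empty_stream_and_bad_uncertainty_rejected(self):
        ph = water_cube_phantom(side_mm=80.0, voxel_mm=4.0)
        with pytest.raises(ValueError, match="empty"):
            simulate_dose((np.zeros((0, 3)), np.zeros((0, 3)), np.zeros(0)), ph)
        with pytest.raises(ValueError, match="uncertainty"):
            simulate_dose(parallel_beam, ph, target_uncertainty=-1.0)


class TestScaleDose:
    def _grid(self):
        return DoseGrid(values=np.ones((4, 4, 4)), uncertainty=None,
                        voxel_size_mm=2.0, origin_mm=(0, 0, 0), histories=100)

    def test_identity_when_fluence_equals_histories(self):
        out = scale_dose(self._grid(), integral_fluence=100.0, histories=100)
        np.testing.assert_array_equal(out.values, np.ones((4, 4, 4)))

    def test_linearity_in_fluence(self):
        a = scale_dose(self._grid(), 50.0, 100)
        b = scale_dose(self._grid(), 100.0, 100)
        np.testing.assert_allclose(b.values, 2 * a.values)

    def test_zero_histories_rejected(self):
        with pytest.raises(ValueError):
            scale_dose(self._grid(), 1.0, 0)

    def test_scaled_dose_independent_of_history_count(self):
        """Two runs with different H agree after scaling (same expected fluence)."""
        ph = water_cube_phantom(side_mm=80.0, voxel_mm=4.0, iso_depth_mm=40.0)
        vals = []
        for h in (150000, 300000):
            grid, used = simulate_dose(parallel_beam, ph, max_histories=h, seed=21)
            scaled = scale_dose(grid, integral_fluence=1.0, histories=used)
            sel = scaled.values > 0.5 * scaled.values.max()
            vals.append((scaled, sel))
        (a, sel_a), (b, sel_b) = vals
        sel = sel_a & sel_b
        ratio = a.values[sel] / b.values[sel]
        assert ratio.mean() == pytest.approx(1.0, abs=0.03)


class TestMedianFilter:
    def test_constant_grid_unchanged(self):
        g = np.full((8, 8, 8), 3.5)
        np.testing.assert_array_equal(median_filter(g, 3), g)

    def test_spike_removed(self):
        g = np.ones((7, 7, 7))
        g[3, 3, 3] = 100.0
        out = median_filter(g, 1)
        assert out[3, 3, 3] == 1.0

    def test_radius_zero_is_identity(self):
        rng = np.random.default_rng(0)
        g = rng.random((5, 6, 7))
        np.testing.assert_array_equal(median_filter(g, 0), g)

    @pytest.mark.parametrize("radius", [1, 3])
    def test_matches_brute_force_with_boundary_clipping(self, radius):
        rng = np.random.default_rng(5)
        g = rng.random((9, 8, 10))
        out = median_filter(g, radius)
        for idx in [(0, 0, 0), (4, 4, 5), (8, 7, 9), (1, 6, 2)]:
            i, j, k = idx
            nb = g[max(0, i - radius):i + radius + 1,
                   max(0, j - radius):j + radius + 1,
                   max(0, k - radius):k + radius + 1]
            assert out[idx] == np.median(nb)

    def test_region_restricted_filter_matches_full(self):
        rng = np.random.default_rng(6)
        g = rng.random((12, 12, 12))
        full = median_filter(g, 2)
        part = median_filter(g, 2, region=((4, 8), (4, 8), (4, 8)))
        np.testing.assert_array_equal(part[4:8, 4:8, 4:8], full[4:8, 4:8, 4:8])
        np.testing.assert_array_equal(part[0:4], g[0:4])

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.ones((3, 3, 3)), -1)


class TestHUConversion:
    def test_water_at_zero_hu(self):
        rho, mat = hu_to_density(0.0)
        assert rho == pytest.approx(1.0, abs=0.01)
        assert mat == 2  # soft tissue / water-like

    def test_table_knots_exact(self):
        cal = HUCalibration()
        for hu, red in cal.hu_to_red:
            rho, _ = hu_to_density(hu, cal)
            assert rho == pytest.approx(
                cal.red_to_density_slope * red + cal.red_to_density_offset
            )

    def test_below_table_clamps_to_air(self):
        rho, mat = hu_to_density(-2000.0)
        assert rho == pytest.approx(0.001)
        assert mat == 0

    def test_monotone_in_hu_for_random_tables(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            hu_knots = np.sort(rng.uniform(-1000, 2000, 6))
            red_knots = np.sort(rng.uniform(0, 2.0, 6))
            cal = HUCalibration(hu_to_red=np.column_stack([hu_knots, red_knots]))
            hu = np.linspace(-1100, 2100, 200)
            rho, _ = hu_to_density(hu, cal)
            assert np.all(np.diff(rho) >= -1e-12)

    def test_non_monotone_table_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            HUCalibration(hu_to_red=np.array([[0.0, 1.0], [-10.0, 1.2]]))
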