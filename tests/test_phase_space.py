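"""Phase-space geometry, fluence composition and particle sampling."""

import numpy as np
import pytest
from scipy import stats

from phspdose.aperture import Aperture, N_LEAF_PAIRS, Segment, make_square_field
from phspdose.beam_model import MachineGeometry, VirtualSource
from phspdose.phase_space import (
    PhaseSpaceMap,
    SourceFluence,
    build_grid,
    build_phase_space,
    compose_fluence,
    primary_divergent_coords,
    project_to_plane,
    raw_fluence,
    sample_particle_arrays,
    sample_particles,
    sigma_at_plane,
)

GEO = MachineGeometry()  # packaged defaults: d=1000, p=548, c=401.8


class TestGeometry:
    def test_grid_corner_and_center(self):
        x_d, y_d = build_grid(GEO)
        assert x_d.shape == (800,) and y_d.shape == (800,)
        assert (x_d[0], y_d[0]) == (-200.0, -200.0)
        assert x_d[400] == pytest.approx(0.0, abs=1e-12)
        assert x_d[799] == pytest.approx(199.5, abs=1e-12)

    def test_projection_on_axis_is_axial(self):
        for s_n in (0.0, 150.0):
            (xp, yp, zp), (ux, uy, uz) = project_to_plane(0.0, 0.0, s_n, GEO)
            assert (xp, yp, zp) == (0.0, 0.0, 548.0)
            assert (ux, uy) == (0.0, 0.0) and uz == 1.0

    def test_projection_closed_forms(self):
        (xp, _, _), _ = project_to_plane(100.0, 0.0, 0.0, GEO)
        assert xp == pytest.approx(100.0 * 548.0 / 1000.0, rel=1e-12)
        (xp, _, _), _ = project_to_plane(100.0, 0.0, 150.0, GEO)
        assert xp == pytest.approx(100.0 * 398.0 / 850.0, rel=1e-12)

    def test_projection_direction_is_unit_and_through_source(self):
        (xp, yp, zp), (ux, uy, uz) = project_to_plane(123.0, -47.0, 150.0, GEO)
        assert ux**2 + uy**2 + uz**2 == pytest.approx(1.0, abs=1e-12)
        # the ray from (0, 0, s_n) through the plane point has this direction
        r = np.array([xp, yp, zp - 150.0])
        np.testing.assert_allclose(r / np.linalg.norm(r), [ux, uy, uz], atol=1e-12)

    def test_source_below_plane_rejected(self):
        with pytest.raises(ValueError):
            project_to_plane(0.0, 0.0, 548.0, GEO)

    def test_primary_divergent_identity_for_primary_source(self):
        xp, yp, r = primary_divergent_coords(123.4, -56.7, 0.0, GEO)
        assert xp == pytest.approx(123.4, rel=1e-12)
        assert yp == pytest.approx(-56.7, rel=1e-12)
        assert r == pytest.approx(np.hypot(123.4, 56.7), rel=1e-12)

    def test_primary_divergent_closed_form(self):
        xp, _, _ = primary_divergent_coords(100.0, 0.0, 150.0, GEO)
        assert xp == pytest.approx(100.0 * 1000.0 * 251.8 / (401.8 * 850.0), rel=1e-12)
        _, _, r0 = primary_divergent_coords(0.0, 0.0, 150.0, GEO)
        assert r0 == 0.0

    def test_source_below_collimator_rejected(self):
        with pytest.raises(ValueError):
            primary_divergent_coords(1.0, 1.0, 402.0, GEO)

    def test_sigma_at_plane_closed_forms(self):
        s1 = VirtualSource(position_mm=0.0, weight=0.94, sigma_x_mm=1.5, sigma_y_mm=1.5)
        s2 = VirtualSource(position_mm=150.0, weight=0.06, sigma_x_mm=24.0, sigma_y_mm=24.0)
        sx, sy = sigma_at_plane(s1, GEO)
        assert sx == pytest.approx(1.5 * 146.2 / 401.8, rel=1e-12)
        sx2, _ = sigma_at_plane(s2, GEO)
        assert sx2 == pytest.approx(24.0 * 146.2 / 251.8, rel=1e-12)


class TestRawFluence:
    def test_open_center_of_flattened_field(self, flattened_model):
        phi = raw_fluence(flattened_model, make_square_field(100.0), 0.0)
        assert phi[400, 400] == pytest.approx(1.000)

    def test_blocked_cell_is_zero(self, flattened_model):
        phi = raw_fluence(flattened_model, make_square_field(100.0), 0.0)
        assert phi[0, 0] == 0.0  # far corner: outside jaws, tau = 0

    def test_fff_value_at_100mm_off_axis(self, fff_model):
        phi = raw_fluence(fff_model, make_square_field(400.0), 0.0)
        # grid row at x = 100 mm, y = 0: r' = 100 -> tabulated 0.684
        assert phi[600, 400] == pytest.approx(0.684)

    def test_flattened_vs_fff_profile_shape(self, flattened_model, fff_model):
        ap = make_square_field(400.0)
        flat = raw_fluence(flattened_model, ap, 0.0)
        fff = raw_fluence(fff_model, ap, 0.0)
        centre = (400, 400)
        off = (600, 400)  # 100 mm off axis
        assert fff[off] / fff[centre] <= 0.70
        assert flat[off] / flat[centre] >= 1.0


class TestComposeFluence:
    def test_fft_matches_direct_convolution(self, flattened_model):
        import dataclasses

        small_geo = dataclasses.replace(
            flattened_model.geometry, grid_size_i=64, grid_size_j=64,
            grid_resolution_x_mm=2.0, grid_resolution_y_mm=2.0,
            grid_edge_x_mm=-64.0, grid_edge_y_mm=-64.0,
        )
        model = dataclasses.replace(flattened_model, geometry=small_geo)
        seg = Segment(aperture=make_square_field(60.0), monitor_units=50.0)
        for src in model.sources:
            fft = compose_fluence(model, seg, source=src, method="fft")
            direct = compose_fluence(model, seg, source=src, method="direct")
            ref = np.abs(direct).max()
            np.testing.assert_allclose(fft, direct, atol=1e-6 * ref)

    def test_total_fluence_conserved_by_convolution(self, flattened_model):
        seg = Segment(aperture=make_square_field(50.0), monitor_units=100.0)
        g = flattened_model.geometry
        area = seg.aperture.open_area_mm2()
        f_a = flattened_model.scatter_factors.factor_for_area(area)
        for src in flattened_model.sources:
            phi = raw_fluence(flattened_model, seg.aperture, src.position_mm)
            composed = compose_fluence(flattened_model, seg, source=src)
            expected = (
                src.weight * seg.monitor_units * f_a * flattened_model.calibration
                * g.grid_resolution_x_mm * g.grid_resolution_y_mm * phi.sum()
            )
            assert composed.sum() == pytest.approx(expected, rel=1e-6)

    def test_single_cell_aperture_yields_gaussian(self, flattened_model):
        # opening much smaller than the source width acts as a delta function:
        # the composed fluence is the (projected) source distribution itself
        bank_a = np.zeros(N_LEAF_PAIRS)
        bank_b = np.zeros(N_LEAF_PAIRS)
        bank_a[40] = -0.25  # leaf band [0, 5): single 0.5 mm opening at the axis
        bank_b[40] = 0.25
        ap = Aperture(y_jaws_mm=(0.0, 0.5), mlc_bank_a_mm=bank_a, mlc_bank_b_mm=bank_b)
        seg = Segment(aperture=ap, monitor_units=100.0)
        src = flattened_model.sources[1]  # broad source: sigma >> opening
        composed = compose_fluence(flattened_model, seg, source=src)
        i0, j0 = np.unravel_index(np.argmax(composed), composed.shape)
        sx, sy = sigma_at_plane(src, flattened_model.geometry)
        g = flattened_model.geometry
        scale = (g.phase_plane_mm - src.position_mm) / (
            g.source_to_isocenter_mm - src.position_mm
        )
        sig_cells = sx / (g.grid_resolution_x_mm * scale)
        profile = composed[:, j0] / composed[i0, j0]
        i = np.arange(len(profile))
        gauss = np.exp(-0.5 * ((i - i0) / sig_cells) ** 2)
        sel = gauss > 1e-3
        np.testing.assert_allclose(profile[sel], gauss[sel], atol=0.01)

    def test_doubling_mu_doubles_total(self, flattened_model):
        seg1 = Segment(aperture=make_square_field(50.0), monitor_units=100.0)
        seg2 = Segment(aperture=make_square_field(50.0), monitor_units=200.0)
        ps1 = build_phase_space(flattened_model, seg1)
        ps2 = build_phase_space(flattened_model, seg2)
        assert ps2.integral_fluence == pytest.approx(2 * ps1.integral_fluence, rel=1e-12)

    def test_closed_aperture_composes_to_zero_and_sampling_errors(self, flattened_model):
        ap = Aperture(y_jaws_mm=(-50.0, 50.0),
                      mlc_bank_a_mm=np.zeros(N_LEAF_PAIRS),
                      mlc_bank_b_mm=np.zeros(N_LEAF_PAIRS))
        seg = Segment(aperture=ap, monitor_units=100.0)
        ps = build_phase_space(flattened_model, seg)
        assert ps.integral_fluence == 0.0
        with pytest.raises(ValueError, match="empty beam"):
            sample_particle_arrays(ps, 100, 0)


def _uniform_four_cell_map(flattened_model):
    """Single-source map with four equal cells, everything else masked out."""
    import dataclasses

    geo = dataclasses.replace(
        flattened_model.geometry, grid_size_i=2, grid_size_j=2,
        grid_resolution_x_mm=1.0, grid_resolution_y_mm=1.0,
        grid_edge_x_mm=-1.0, grid_edge_y_mm=-1.0,
    )
    model = dataclasses.replace(flattened_model, geometry=geo)
    src = model.sources[0]
    phi = np.full((2, 2), 5.0)
    sf = SourceFluence(source=src, phi_prime=phi, plane_spacing_mm=(0.548, 0.548),
                       mask=np.ones((2, 2), dtype=bool))
    return PhaseSpaceMap(beam=model, sources=[sf])


class TestSampling:
    def test_uniform_cells_sampled_uniformly(self, flattened_model):
        ps = _uniform_four_cell_map(flattened_model)
        n = 40000
        pos, _, _ = sample_particle_arrays(ps, n, 123, jitter=False)
        # cells project to plane coordinates {-0.548, 0.0} on each axis
        xneg, yneg = pos[:, 0] < -0.25, pos[:, 1] < -0.25
        counts = np.array([
            (xneg & yneg).sum(),
            (xneg & ~yneg).sum(),
            (~xneg & yneg).sum(),
            (~xneg & ~yneg).sum(),
        ])
        sigma = np.sqrt(n * 0.25 * 0.75)
        assert np.all(np.abs(counts - n * 0.25) < 3 * sigma)

    def test_energy_lines_match_spectrum(self, flattened_model):
        seg = Segment(aperture=make_square_field(100.0), monitor_units=100.0)
        ps = build_phase_space(flattened_model, seg)
        n = 100000
        _, _, energy = sample_particle_arrays(ps, n, 7)
        lines = flattened_model.spectrum.energies_mev
        probs = flattened_model.spectrum.probabilities
        counts = np.array([(energy == e).sum() for e in lines])
        chi2 = ((counts - n * probs) ** 2 / (n * probs)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=len(lines) - 1)

    def test_masked_out_cells_never_sampled(self, flattened_model):
        seg = Segment(aperture=make_square_field(30.0), monitor_units=100.0)
        ps = build_phase_space(flattened_model, seg)
        pos, _, _ = sample_particle_arrays(ps, 20000, 3, jitter=False)
        # reconstruct cell values: every particle must come from a masked-in cell
        beam_max = max(sf.phi_prime.max() for sf in ps.sources)
        x_d = np.arange(800) * 0.5 - 200.0
        ok = np.zeros(len(pos), dtype=bool)
        for sf in ps.sources:
            g = ps.geometry
            s = sf.source.position_mm
            scale = (g.phase_plane_mm - s) / (g.source_to_isocenter_mm - s)
            ii = np.rint((pos[:, 0] / scale - x_d[0]) / 0.5).astype(int)
            jj = np.rint((pos[:, 1] / scale - x_d[0]) / 0.5).astype(int)
            exact = (np.abs(x_d[np.clip(ii, 0, 799)] * scale - pos[:, 0]) < 1e-9) & (
                np.abs(x_d[np.clip(jj, 0, 799)] * scale - pos[:, 1]) < 1e-9
            )
            val = sf.phi_prime[np.clip(ii, 0, 799), np.clip(jj, 0, 799)]
            ok |= exact & (val >= 0.01 * beam_max)
        assert ok.all()

    def test_seed_reproducibility(self, flattened_model):
        seg = Segment(aperture=make_square_field(50.0), monitor_units=100.0)
        ps = build_phase_space(flattened_model, seg)
        a = sample_particle_arrays(ps, 5000, 42)
        b = sample_particle_arrays(ps, 5000, 42)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        c = sample_particle_arrays(ps, 5000, 43)
        assert not np.array_equal(a[0], c[0])

    def test_particles_lie_on_plane_and_travel_forward(self, flattened_model):
        seg = Segment(aperture=make_square_field(50.0), monitor_units=100.0)
        ps = build_phase_space(flattened_model, seg)
        pos, direction, energy = sample_particle_arrays(ps, 10000, 0)
        np.testing.assert_allclose(pos[:, 2], 548.0)
        np.testing.assert_allclose(np.linalg.norm(direction, axis=1), 1.0, atol=1e-9)
        assert (direction[:, 2] > 0).all()
        assert ((energy >= 0.5) & (energy <= 6.0)).all()

    def test_ray_passes_through_isocenter_grid_point(self, flattened_model):
        """Extending a particle's ray to z = d recovers its generating grid point."""
        seg = Segment(aperture=make_square_field(50.0), monitor_units=100.0)
        ps = build_phase_space(flattened_model, seg)
        pos, direction, _ = sample_particle_arrays(ps, 5000, 9, jitter=True)
        g = ps.geometry
        t = (g.source_to_isocenter_mm - pos[:, 2]) / direction[:, 2]
        x_iso = pos[:, 0] + t * direction[:, 0]
        # intra-cell jitter at the plane magnifies to at most one full cell at iso
        x_d = np.arange(800) * 0.5 - 200.0
        nearest = x_d[np.argmin(np.abs(x_iso[:, None] - x_d[None, :]), axis=1)]
        assert np.abs(x_iso - nearest).max() <= 0.5 + 1e-9

    def test_h5_and_text_export_round_trip(self, flattened_model, tmp_path):
        import h5py

        from phspdose.phase_space import export_phase_space_h5, export_phase_space_text

        seg = Segment(aperture=make_square_field(50.0), monitor_units=100.0)
        ps = build_phase_space(flattened_model, seg)
        h5_path = tmp_path / "phsp.h5"
        export_phase_space_h5(h5_path, ps, count=500, seed=11)
        with h5py.File(h5_path) as f:
            rec = f["records"][:]
            assert rec.shape == (500, 8)
            assert f.attrs["beam_quality"] == "flattened"
            assert f.attrs["seed"] == 11
        txt_path = tmp_path / "phsp.txt"
        export_phase_space_text(txt_path, ps, count=500, seed=11)
        rec_txt = np.loadtxt(txt_path)
        np.testing.assert_allclose(rec_txt, rec, rtol=1e-6)

    def test_record_iterator_matches_arrays(self, flattened_model):
        seg = Segment(aperture=make_square_field(50.0), monitor_units=100.0)
        ps = build_phase_space(flattened_model, seg)
        records = list(sample_particles(ps, 10, seed=5))
        pos, direction, energy = sample_particle_arrays(ps, 10, 5)
        assert len(records) == 10
        np.testing.assert_allclose(records[3].position_mm, pos[3])
        np.testing.assert_allclose(records[3].direction, direction[3])
        assert records[3].energy_mev == energy[3]
        assert records[3].statistical_weight == 1.0
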