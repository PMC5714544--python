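import numpy as np
import pytest

from sbrt4d.beams import Beam, BeamSet, generate_candidates
from sbrt4d.dose_engines import (
    AIR,
    BONE,
    SOFT_TISSUE,
    BeamModel,
    DoseGrid,
    KernelSurrogate,
    RayTracingEPL,
    UncertaintySpec,
    apply_statistical_noise,
    assign_material,
    epl_dose,
    mc_surrogate_dose,
    radiological_depth,
    uncertainty_map,
)
from sbrt4d.phantom4d import GridSpec


class TestAssignMaterial:
    @pytest.mark.parametrize(
        "rho, label",
        [
            (0.05, AIR),
            (0.0, AIR),
            (0.1, SOFT_TISSUE),  # boundary inclusive to soft tissue
            (1.0, SOFT_TISSUE),
            (1.125, SOFT_TISSUE),  # boundary inclusive to soft tissue
            (1.2, BONE),
            (1.6, BONE),
        ],
    )
    def test_piecewise_rule(self, rho, label):
        assert assign_material(np.array([[[rho]]]))[0, 0, 0] == label

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            assign_material(np.array([-0.1]))


class TestBeamModel:
    def test_tpr_is_one_at_dmax(self, beam_model):
        assert beam_model.tpr(beam_model.dmax_cm) == pytest.approx(1.0, abs=1e-9)

    def test_tpr_coverage_error(self, beam_model):
        with pytest.raises(ValueError, match="TPR table"):
            beam_model.tpr(1000.0)

    def test_ocr_unity_on_axis_and_nonincreasing(self, beam_model):
        r = np.linspace(0.0, 80.0, 200)
        ocr = beam_model.ocr(r, 25.0)
        assert ocr[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ocr) <= 1e-12)

    def test_tpr_csv_roundtrip(self, beam_model, tmp_path):
        path = tmp_path / "tpr.csv"
        beam_model.tpr_to_csv(path)
        loaded = BeamModel.tpr_from_csv(path, dmax_cm=beam_model.dmax_cm)
        assert np.allclose(loaded.tpr_values, beam_model.tpr_values)


class TestRadiologicalDepth:
    def test_uniform_water_identity(self):
        grid = GridSpec.centered((20, 20, 60), (2.0, 2.0, 2.0))
        rho = np.ones(grid.shape)
        # 100 mm geometric path inside water is 10 cm water-equivalent
        d = radiological_depth(rho, grid, (0, 0, 500.0), (0, 0, 59.0 - 100.0))
        _, hi = grid.bounding_box()
        geom_inside = (hi[2] - (59.0 - 100.0)) / 10.0  # from the grid boundary
        assert d == pytest.approx(geom_inside, rel=1e-6)

    def test_slab_closed_form(self):
        """3 cm water + 5 cm lung(0.25) + 2 cm water = 6.25 cm equivalent."""
        grid = GridSpec.centered((20, 20, 50), (2.0, 2.0, 2.0))
        x, y, z = grid.meshgrid()
        rho = np.ones(grid.shape)
        top = 49.0  # bbox upper z face is at 50
        rho[(z <= top - 30) & (z > top - 80)] = 0.25
        point = (0.0, 0.0, 50.0 - 100.0)
        d = radiological_depth(rho, grid, (0, 0, 400.0), point)
        assert d == pytest.approx(3.0 + 5.0 * 0.25 + 2.0, rel=1e-6)

    def test_air_path_is_zero(self):
        grid = GridSpec.centered((10, 10, 10), (2.0, 2.0, 2.0))
        rho = np.zeros(grid.shape)
        assert radiological_depth(rho, grid, (0, 0, 100.0), (0, 0, 0.0)) == 0.0

    def test_matches_brute_force_on_random_oblique_rays(self):
        """Exact traversal agrees with a dense sampled line integral."""
        rng = np.random.default_rng(42)
        grid = GridSpec.centered((16, 16, 16), (2.5, 2.5, 2.5))
        rho = rng.uniform(0.0, 1.6, grid.shape)
        lo, hi = grid.bounding_box()
        for _ in range(10):
            src = np.array([90.0, 0, 0]) + rng.uniform(-20, 20, 3)
            pt = rng.uniform(lo + 2, hi - 2)
            d = radiological_depth(rho, grid, src, pt)
            ts = (np.arange(200_000) + 0.5) / 200_000
            ps = src + ts[:, None] * (pt - src)
            inside = np.all((ps >= lo) & (ps <= hi), axis=1)
            idx = np.clip(((ps - lo) // grid.spacing[0]).astype(int), 0, 15)
            vals = np.where(inside, rho[idx[:, 0], idx[:, 1], idx[:, 2]], 0.0)
            brute = vals.sum() * np.linalg.norm(pt - src) / len(ts) / 10.0
            assert d == pytest.approx(brute, abs=5e-3)

    def test_source_inside_grid_rejected(self):
        grid = GridSpec.centered((10, 10, 10), (2.0, 2.0, 2.0))
        rho = np.ones(grid.shape)
        with pytest.raises(ValueError, match="outside"):
            radiological_depth(rho, grid, (0, 0, 0), (1, 1, 1))


class TestEPLDose:
    def test_calibration_identity(self, water_grid, axial_beam, fine_epl):
        """100 MU on the axis at dmax depth and SAD gives 100 cGy."""
        grid, rho = water_grid
        bs = BeamSet([axial_beam], np.array([100.0]))
        mask = np.zeros(grid.shape, dtype=bool)
        mask[30, 30, :] = True
        dose = fine_epl.dose(bs, rho, grid, mask)
        at_dmax = dose.values[30, 30, np.argmin(np.abs(grid.axis_coords(2) - 46.0))]
        assert at_dmax == pytest.approx(100.0, rel=0.02)

    def test_lung_slab_upstream_uses_equivalent_depth(self, axial_beam, fine_epl, beam_model):
        """With 6.25 cm equivalent path at 10 cm geometric depth, the dose
        equals the water TPR at 6.25 cm (times inverse square)."""
        grid = GridSpec.centered((60, 60, 80), (2.0, 2.0, 2.0))
        x, y, z = grid.meshgrid()
        rho = np.zeros(grid.shape)
        surf = 61.0
        rho[z <= surf] = 1.0
        rho[(z <= surf - 30) & (z > surf - 80)] = 0.25
        beam = Beam(source=(0, 0, 900.0), direction=(0, 0, -1.0), aperture_radius_mm=25.0)
        pt = np.array([[0.0, 0.0, surf - 100.0]])
        dose = fine_epl.point_dose(beam, rho, grid, pt)[0]
        dist = 900.0 - (surf - 100.0)
        expected = beam_model.tpr(6.25) * (800.0 / dist) ** 2
        assert dose == pytest.approx(expected, rel=0.02)

    def test_zero_weights_zero_dose(self, water_grid, axial_beam):
        grid, rho = water_grid
        dose = epl_dose(BeamSet([axial_beam]), rho, grid)
        assert np.all(dose.values == 0.0)

    def test_linearity_in_weights(self, water_grid, axial_beam, fine_epl):
        grid, rho = water_grid
        beam2 = Beam(source=(100.0, 0.0, 830.0), direction=tuple(-np.array([100.0, 0, 830]) / np.linalg.norm([100, 0, 830])), aperture_radius_mm=15.0)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[28:33, 28:33, 20:40] = True
        d1 = fine_epl.dose(BeamSet([axial_beam, beam2], [2.0, 0.0]), rho, grid, mask).values
        d2 = fine_epl.dose(BeamSet([axial_beam, beam2], [0.0, 3.0]), rho, grid, mask).values
        d12 = fine_epl.dose(BeamSet([axial_beam, beam2], [2.0, 3.0]), rho, grid, mask).values
        assert np.allclose(d12, d1 + d2, rtol=1e-9, atol=1e-12)


class TestKernelSurrogate:
    def test_matches_epl_in_homogeneous_water_in_field(self, water_grid, axial_beam, fine_epl, fine_surrogate):
        """Redistribution is the identity on a broad flat field far from
        density interfaces: agreement within 2% in-field."""
        grid, rho = water_grid
        pts = np.array([[0.0, 0.0, zc] for zc in np.arange(-30.0, 40.0, 4.0)])
        de = fine_epl.point_dose(axial_beam, rho, grid, pts)
        dm = fine_surrogate.point_dose(axial_beam, rho, grid, pts)
        assert np.abs(dm / de - 1.0).max() < 0.02

    def test_sigma_zero_is_exactly_epl(self, water_grid, axial_beam, beam_model):
        grid, rho = water_grid
        epl = RayTracingEPL(beam_model)
        sur = KernelSurrogate(beam_model, sigma0_mm=0.0)
        pts = np.array([[5.0, -3.0, 10.0], [0.0, 0.0, 46.0]])
        assert np.array_equal(epl.point_dose(axial_beam, rho, grid, pts), sur.point_dose(axial_beam, rho, grid, pts))

    def test_negative_sigma_rejected(self, beam_model):
        with pytest.raises(ValueError):
            KernelSurrogate(beam_model, sigma0_mm=-1.0)

    def test_energy_redistribution_conserves_energy(self, beam_model):
        """Total dose*density*volume matches the unsmoothed primary within
        1% when the kernel support stays inside the grid."""
        grid = GridSpec.centered((72, 72, 60), (2.0, 2.0, 2.0))
        x, y, z = grid.meshgrid()
        rho = np.zeros(grid.shape)
        body = (np.abs(x) <= 64) & (np.abs(y) <= 64) & (z <= 55)
        rho[body] = 1.0
        rho[body & (x > 8)] = 0.25
        beam = Beam(source=(0, 0, 856.0), direction=(0, 0, -1.0), aperture_radius_mm=18.0)
        epl = RayTracingEPL(beam_model, step_w_mm=1.5, lateral_spacing_mm=1.5)
        sur = KernelSurrogate(beam_model, step_w_mm=1.5, lateral_spacing_mm=1.5, spread_truncate_sigmas=4.0)
        bs = BeamSet([beam], [100.0])
        interior = body & (z <= 40) & (z >= -40)
        d_epl = epl.dose(bs, rho, grid, interior).values
        d_sur = sur.dose(bs, rho, grid, interior)[0].values
        e_epl = float((d_epl * rho).sum())
        e_sur = float((d_sur * rho).sum())
        assert e_sur == pytest.approx(e_epl, rel=0.01)

    def test_interface_underdose_monotone_in_lung_density(self, beam_model):
        """Near a lateral soft-tissue/lung interface the surrogate dose on
        the dense side is below the ray-tracing dose, and the deficit grows
        as the lung density drops."""
        grid = GridSpec.centered((60, 60, 60), (2.0, 2.0, 2.0))
        x, y, z = grid.meshgrid()
        beam = Beam(source=(0, 0, 856.0), direction=(0, 0, -1.0), aperture_radius_mm=22.0)
        epl = RayTracingEPL(beam_model, step_w_mm=1.5, lateral_spacing_mm=2.0)
        sur = KernelSurrogate(beam_model, step_w_mm=1.5, lateral_spacing_mm=2.0)
        # tumor side x<0, lung side x>0; evaluate shallow (small depth
        # difference between the two columns) just inside the tumor side
        pts = np.array([[xo, 0.0, 36.0] for xo in (-1.0, -3.0)])
        deficits = []
        for rho_lung in (0.5, 0.25, 0.1):
            rho = np.zeros(grid.shape)
            surf = z <= 41
            rho[surf] = 1.0
            rho[surf & (x > 0)] = rho_lung
            de = epl.point_dose(beam, rho, grid, pts)
            dm = sur.point_dose(beam, rho, grid, pts)
            deficits.append(float((dm - de).mean()))
        assert all(d < 0 for d in deficits)
        assert deficits[0] > deficits[1] > deficits[2]  # more negative as rho drops


class TestNoiseAndUncertainty:
    def test_relative_sd_anchored_at_dmax(self):
        """At D = Dmax the relative SD is sigma; at Dmax/2 it is 2*sigma."""
        rng_shape = (40, 40, 40)
        dose = np.full(rng_shape, 100.0)
        dose[:, :, 20:] = 50.0
        spec = UncertaintySpec(0.04, seed=7)
        noisy = apply_statistical_noise(dose, spec)
        rel_hi = (noisy[:, :, :20] / 100.0 - 1.0).std()
        rel_lo = (noisy[:, :, 20:] / 50.0 - 1.0).std()
        assert rel_hi == pytest.approx(0.04, rel=0.05)
        assert rel_lo == pytest.approx(0.08, rel=0.05)

    def test_noise_seeded_and_iid(self):
        dose = np.full((30, 30, 30), 80.0)
        spec = UncertaintySpec(0.04, seed=11)
        a = apply_statistical_noise(dose, spec)
        b = apply_statistical_noise(dose, spec)
        c = apply_statistical_noise(dose, UncertaintySpec(0.04, seed=12))
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)
        # neighbouring voxels are uncorrelated
        r = np.corrcoef(a[:-1].ravel(), a[1:].ravel())[0, 1]
        assert abs(r) < 0.03

    def test_zero_dose_voxels_stay_zero(self):
        dose = np.zeros((5, 5, 5))
        dose[2, 2, 2] = 100.0
        noisy = apply_statistical_noise(dose, UncertaintySpec(0.04, seed=1))
        assert np.all(noisy[dose == 0] == 0.0)
        assert np.all(noisy >= 0.0)

    def test_uncertainty_map_proportional_to_inverse_dose(self):
        grid = GridSpec.centered((4, 4, 4), (1, 1, 1))
        values = np.full(grid.shape, 25.0)
        values[0, 0, 0] = 100.0
        umap = uncertainty_map(DoseGrid(values, grid), UncertaintySpec(0.01))
        assert umap.values[0, 0, 0] == pytest.approx(0.01)
        assert umap.values[1, 1, 1] == pytest.approx(0.04)  # Dmax/4 -> 4x
        assert umap.values.min() == pytest.approx(0.01)  # minimum at Dmax

    def test_uncertainty_map_all_zero_dose_rejected(self):
        grid = GridSpec.centered((3, 3, 3), (1, 1, 1))
        with pytest.raises(ValueError):
            uncertainty_map(DoseGrid(np.zeros(grid.shape), grid), UncertaintySpec(0.01))

    def test_mc_surrogate_dose_returns_uncertainty(self, water_grid, axial_beam):
        grid, rho = water_grid
        mask = np.zeros(grid.shape, dtype=bool)
        mask[28:33, 28:33, 25:35] = True
        dose, unc = mc_surrogate_dose(
            BeamSet([axial_beam], [100.0]), rho, grid, mask, uncertainty=UncertaintySpec(0.04, seed=3)
        )
        assert unc is not None and unc.sigma_at_dmax == 0.04
        assert np.all(dose.values >= 0.0)
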