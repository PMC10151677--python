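"""Transport oracles, conservation, uncertainty scaling, beams and fits."""

import numpy as np
import pytest
from scipy import stats

from expanderdose import kernels, mc
from expanderdose.artifacts import DensityGrid
from expanderdose.beams import ArcSpec, BeamSpec, CalibrationModel
from expanderdose.dosegrid import calibrate
from expanderdose.materials import (
    NDFEB,
    WATER,
    build_spectrum_6mv,
    mixture_mass_attenuation,
    transmission,
)
from expanderdose.pdd import fit_pdd_exponential
from expanderdose.raytrace import raytrace_dose


def _mono_beam(e=2.0, fx=10.0, fz=10.0):
    return BeamSpec(build_spectrum_6mv(monoenergetic=e), fx, fz, 100.0, 0.0, 1.0)


class TestWoodcockOracle:
    def test_first_interaction_depths_match_exponential(self, water_grid):
        """Woodcock delta tracking reproduces Exp(mu) free flight in a
        homogeneous medium (survival beyond d equals exp(-mu d), 3 sigma)."""
        e = 2.0
        acc = mc._McAccumulator(water_grid, "analog")
        n = 40_000
        depths = kernels.woodcock_first_depths(
            n, 123, e,
            0.0, -100.0, 0.0, 0.0, 1.0, 0.0,
            acc.rho, acc.mat, acc.mu_tab, acc.mumaj,
            acc.loge0, acc.invd, mc.NE,
            acc.lo[0], acc.lo[1], acc.lo[2],
            acc.sp[0], acc.sp[1], acc.sp[2],
            acc.nx, acc.ny, acc.nz,
        )
        mu = mixture_mass_attenuation(WATER, e)
        interacted = depths[depths >= 0]
        # depth measured from grid entry; survival to 10 cm
        for d in (3.0, 10.0):
            p_exp = np.exp(-mu * d)
            frac = ((depths < 0) | (depths > d)).mean()
            # escapes are photons surviving the full 20 cm; they count as > d
            sigma = np.sqrt(p_exp * (1 - p_exp) / len(depths))
            assert abs(frac - p_exp) < 3.5 * sigma

    def test_depth_distribution_ks(self, water_grid):
        e = 1.0
        acc = mc._McAccumulator(water_grid, "analog")
        depths = kernels.woodcock_first_depths(
            20_000, 7, e, 0.0, -100.0, 0.0, 0.0, 1.0, 0.0,
            acc.rho, acc.mat, acc.mu_tab, acc.mumaj,
            acc.loge0, acc.invd, mc.NE,
            acc.lo[0], acc.lo[1], acc.lo[2],
            acc.sp[0], acc.sp[1], acc.sp[2],
            acc.nx, acc.ny, acc.nz,
        )
        mu = mixture_mass_attenuation(WATER, e)
        d = depths[depths >= 0]
        depth_max = 20.0  # grid depth, cm: truncated exponential
        cdf = lambda x: (1 - np.exp(-mu * x)) / (1 - np.exp(-mu * depth_max))
        stat, p = stats.kstest(d, cdf)
        assert p > 0.001


class TestEnergyConservation:
    def test_analog_exact(self, water_grid, small_beam):
        d = mc.mc_dose(water_grid, small_beam, 60_000, 3, mode="analog")
        led = d.energy_ledger
        imbalance = abs(led["launched"] - led["deposited"] - led["escaped"]) / led["launched"]
        assert imbalance < 1e-3

    def test_vr_statistical(self, water_grid, small_beam):
        d = mc.mc_dose(water_grid, small_beam, 200_000, 3)
        led = d.energy_ledger
        imbalance = abs(led["launched"] - led["deposited"] - led["escaped"]) / led["launched"]
        assert imbalance < 1e-3


class TestUncertainty:
    @staticmethod
    def _coarse_water():
        sp = np.array([6.0, 6.0, 6.0])
        shape = (28, 34, 28)
        origin = np.array([-81.0, 3.0, -81.0])
        return DensityGrid(origin, sp, np.ones(shape, np.float32),
                           np.zeros(shape, np.uint8), ("water",), "truth")

    def test_inverse_sqrt_scaling_analog(self, small_beam):
        """Median high-dose relative uncertainty of the analog engine
        scales ~ 1/sqrt(N) (log-log slope -0.5 +/- 0.1)."""
        grid = self._coarse_water()
        ns = [150_000, 600_000, 2_400_000]
        meds = []
        for n in ns:
            d = mc.mc_dose(grid, small_beam, n, 11, mode="analog")
            hi = d.dose > 0.5 * d.dose.max()
            meds.append(np.median(d.rel_uncertainty[hi]))
        slope = np.polyfit(np.log(ns), np.log(meds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_vr_uncertainty_decreases_at_least_sqrt(self, water_grid, small_beam):
        """The stratified expected-value engine converges at least as fast
        as 1/sqrt(N) (low-discrepancy sampling is typically faster)."""
        ns = [50_000, 200_000, 800_000]
        meds = []
        for n in ns:
            d = mc.mc_dose(water_grid, small_beam, n, 11)
            hi = d.dose > 0.5 * d.dose.max()
            meds.append(np.median(d.rel_uncertainty[hi]))
        slope = np.polyfit(np.log(ns), np.log(meds), 1)[0]
        assert -1.0 < slope < -0.4

    def test_uncertainty_in_unit_interval(self, water_grid, small_beam):
        d = mc.mc_dose(water_grid, small_beam, 50_000, 2)
        assert np.all(d.rel_uncertainty >= 0)
        assert np.all(d.dose >= 0)


class TestDeterminism:
    def test_same_seed_bit_identical(self, water_grid, small_beam):
        d1 = mc.mc_dose(water_grid, small_beam, 50_000, 42)
        d2 = mc.mc_dose(water_grid, small_beam, 50_000, 42)
        assert np.array_equal(d1.dose, d2.dose)
        assert np.array_equal(d1.rel_uncertainty, d2.rel_uncertainty)

    def test_different_seed_differs(self, water_grid, small_beam):
        d1 = mc.mc_dose(water_grid, small_beam, 50_000, 42)
        d2 = mc.mc_dose(water_grid, small_beam, 50_000, 43)
        assert not np.array_equal(d1.dose, d2.dose)


class TestArc:
    def test_degenerate_arc_equals_static_beam(self, water_grid, spectrum):
        arc = ArcSpec(start_deg=90.0, stop_deg=90.0, field_x_cm=3.0, field_z_cm=3.0, mu=100.0)
        da = mc.arc_dose(water_grid, arc, 40_000, 5, batches=4, spectrum=spectrum)
        beam = BeamSpec(spectrum, 3.0, 3.0, 100.0, 90.0, 100.0)
        db = mc.mc_dose(water_grid, beam, 40_000, 5, batches=4)
        assert np.allclose(da.dose, db.dose)

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            ArcSpec(start_deg=90.0, stop_deg=270.0, cp_spacing_deg=7.0)

    def test_control_angles_ccw_pass_through_zero(self):
        arc = ArcSpec(start_deg=90.0, stop_deg=270.0, direction="ccw", cp_spacing_deg=2.0)
        ang = arc.control_angles()
        assert ang[0] == 90.0 and ang[-1] == 270.0
        assert 0.0 in ang  # anterior crossing
        assert len(ang) == 91

    def test_cylinder_full_arc_azimuthal_uniformity(self, spectrum):
        """A full arc on a cylindrical water phantom gives an azimuthally
        uniform shell dose (rotational symmetry within statistics)."""
        n = 40
        sp = np.array([4.0, 4.0, 4.0])
        origin = np.array([-n * 2 + 2, -n * 2 + 2, -40 + 2])
        xs = origin[0] + sp[0] * np.arange(n)
        r = np.hypot(*np.meshgrid(xs, xs, indexing="ij"))
        density = np.where(r < 70, 1.0, 0.0012)[:, :, None].repeat(20, axis=2).astype(np.float32)
        labels = np.where(r < 70, 0, 1)[:, :, None].repeat(20, axis=2).astype(np.uint8)
        grid = DensityGrid(origin, sp, density, labels, ("water", "air"), "truth")
        arc = ArcSpec(start_deg=0.0, stop_deg=360.0, direction="cw", cp_spacing_deg=10.0,
                      field_x_cm=4.0, field_z_cm=4.0, mu=100.0)
        d = mc.arc_dose(grid, arc, 400_000, 9, batches=4, spectrum=spectrum)
        rr = np.hypot(*np.meshgrid(xs, xs, indexing="ij"))
        shell = (rr > 40) & (rr < 52)
        mid = d.dose[:, :, 10]
        phi = np.arctan2(*np.meshgrid(xs, xs, indexing="ij"))
        vals = []
        for k in range(8):
            sel = shell & (phi >= -np.pi + k * np.pi / 4) & (phi < -np.pi + (k + 1) * np.pi / 4)
            vals.append(mid[sel].mean())
        vals = np.array(vals)
        assert vals.std() / vals.mean() < 0.05

    def test_breast_arc_left_right_symmetry(self, breast_phantom_allox2, spectrum):
        from expanderdose import artifacts, phantoms
        from expanderdose.beams import default_partial_arc

        grid = artifacts.no_port_grid(breast_phantom_allox2)
        d = mc.arc_dose(grid, default_partial_arc(), 400_000, 13, batches=4, spectrum=spectrum)
        _, masks = phantoms.make_shell_contours(breast_phantom_allox2)
        left = d.dose[masks["C_Left"].mask].mean()
        right = d.dose[masks["C_Right"].mask].mean()
        assert abs(left - right) / max(left, right) < 0.02


class TestRaytracer:
    def test_monotone_falloff_beyond_dmax(self, water_grid, small_beam):
        d = raytrace_dose(water_grid, small_beam)
        _, pdd = mc.central_axis_pdd(d)
        ys = d.centers(1)
        sel = ys > 30.0
        assert np.all(np.diff(pdd[sel]) < 0)

    def test_magnet_slab_matches_closed_form(self):
        """Inserting a NdFeB slab attenuates the distal primary dose by the
        closed-form transmission ratio (0.5%)."""
        sp = np.array([4.0, 2.0, 4.0])
        shape = (30, 100, 30)
        origin = np.array([-60 + 2, 1.0, -60 + 2])
        density = np.ones(shape, dtype=np.float32)
        labels = np.zeros(shape, dtype=np.uint8)
        plain = DensityGrid(origin, sp, density.copy(), labels.copy(), ("water", "ndfeb"), "truth")
        t_vox = 2  # 2 voxels x 2 mm = 4 mm slab
        d2 = density.copy()
        l2 = labels.copy()
        d2[:, 30:30 + t_vox, :] = 7.4
        l2[:, 30:30 + t_vox, :] = 1
        slabbed = DensityGrid(origin, sp, d2, l2, ("water", "ndfeb"), "truth")
        beam = _mono_beam()
        e = beam.spectrum.effective_energy
        r0 = raytrace_dose(plain, beam)
        r1 = raytrace_dose(slabbed, beam)
        j = 70  # distal voxel
        i, k = 15, 15
        ratio = r1.dose[i, j, k] / r0.dose[i, j, k]
        t_cm = t_vox * sp[1] / 10.0
        t_ratio = transmission(NDFEB, t_cm, e) / transmission(WATER, t_cm, e)
        # the slab also deepens the water-equivalent depth entering the
        # buildup-and-scatter factor; fold that closed form in as well
        from expanderdose.raytrace import BUILDUP_BETA, SCATTER_SLOPE

        mu_w = mixture_mass_attenuation(WATER, e)
        d_eff0 = (r0.centers(1)[j] - 1.0) / 10.0
        d_eff1 = d_eff0 - np.log(t_ratio) / mu_w
        b = lambda d: (1 - np.exp(-BUILDUP_BETA * d)) * (1 + SCATTER_SLOPE * d)
        assert ratio == pytest.approx(t_ratio * b(d_eff1) / b(d_eff0), rel=0.005)

    def test_radiological_path_scaling(self, small_beam):
        """Doubling density everywhere is equivalent to doubling depth, up
        to the inverse-square factor."""
        sp = np.array([4.0, 2.0, 4.0])
        shape = (30, 120, 30)
        origin = np.array([-60 + 2, 1.0, -60 + 2])
        labels = np.zeros(shape, dtype=np.uint8)
        g1 = DensityGrid(origin, sp, np.ones(shape, np.float32), labels, ("water",), "truth")
        g2 = DensityGrid(origin, sp, 2 * np.ones(shape, np.float32), labels, ("water",), "truth")
        r1 = raytrace_dose(g1, small_beam)
        r2 = raytrace_dose(g2, small_beam)
        i, k = 15, 15
        j = 40  # depth d in doubled grid
        j2 = 80  # depth 2d in unit grid
        d = (r2.centers(1)[j]) / 10.0
        d2 = (r1.centers(1)[j2]) / 10.0
        isl = ((100.0 + d2) / (100.0 + d)) ** 2
        assert r2.dose[i, j, k] / r1.dose[i, j2, k] == pytest.approx(isl, rel=0.01)

    def test_beam_miss_raises(self, water_grid, spectrum):
        beam = BeamSpec(spectrum, 1.0, 1.0, 100.0, 0.0, 1.0, isocenter_mm=(0.0, 0.0, 100000.0))
        with pytest.raises(ValueError):
            raytrace_dose(water_grid, beam)


class TestRaytracerMcAgreement:
    def test_water_pdd_within_3pct_beyond_dmax(self, water_grid, small_beam):
        """The raytracer's buildup-and-scatter parameterization tracks the
        MC water PDD within 3% beyond the buildup region."""
        dmc = mc.mc_dose(water_grid, small_beam, 600_000, 21)
        drt = raytrace_dose(water_grid, small_beam)
        ys, pmc = mc.central_axis_pdd(dmc)
        _, prt = mc.central_axis_pdd(drt)
        sel = (ys > 25.0) & (ys < 190.0)
        jn = np.argmin(np.abs(ys - 100.0))
        ratio = (pmc[sel] / pmc[jn]) / (prt[sel] / prt[jn])
        assert np.max(np.abs(ratio - 1.0)) < 0.03


class TestCalibration:
    def test_reference_delivers_one_cgy_per_mu(self, spectrum):
        cal = mc.calibrate_engine("raytrace", spectrum)
        grid = mc.water_reference_grid()
        beam = BeamSpec(spectrum, 10.0, 10.0, 100.0, 0.0, 100.0)  # 100 MU
        d = calibrate(raytrace_dose(grid, beam), cal)
        _, pdd = mc.central_axis_pdd(d)
        assert pdd.max() == pytest.approx(100.0, rel=1e-6)

    def test_scaling_preserves_ratios(self, water_grid, spectrum):
        cal = CalibrationModel(output_factor=2.5, engine="raytrace")
        beam = BeamSpec(spectrum, 10.0, 10.0, 100.0, 0.0, 1.0)
        d = raytrace_dose(water_grid, beam)
        dc = calibrate(d, cal)
        sel = d.dose > 0
        assert np.allclose(dc.dose[sel] / d.dose[sel], 2.5)

    def test_engine_mismatch_raises(self, water_grid, small_beam):
        cal = CalibrationModel(output_factor=1.0, engine="raytrace")
        d = mc.mc_dose(water_grid, small_beam, 10_000, 1)
        with pytest.raises(ValueError):
            calibrate(d, cal)


class TestPddFit:
    def test_exact_exponential_recovered(self):
        d = np.linspace(2, 20, 50)
        y = 3.0 * np.exp(-0.05 * d)
        fit = fit_pdd_exponential(d, y)
        assert fit.amplitude == pytest.approx(3.0, rel=1e-9)
        assert fit.decay_per_cm == pytest.approx(0.05, rel=1e-9)
        assert fit.value_at_depth == pytest.approx(3.0 * np.exp(-0.5), rel=1e-9)

    def test_noisy_recovery_within_1pct(self):
        rng = np.random.default_rng(3)
        d = np.linspace(4, 16, 60)
        y = 2.0 * np.exp(-0.06 * d) * (1 + rng.normal(0, 0.005, d.size))
        fit = fit_pdd_exponential(d, y)
        assert fit.value_at_depth == pytest.approx(2.0 * np.exp(-0.6), rel=0.01)

    def test_non_monotone_flagged(self):
        d = np.linspace(5, 15, 20)
        y = np.exp(-0.05 * d)
        y[10] *= 1.2
        fit = fit_pdd_exponential(d, y)
        assert fit.warnings

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_pdd_exponential([6, 7, 8], [1, 1, 1])
        d = np.linspace(5, 15, 20)
        y = np.exp(-0.05 * d)
        y[5] = -1.0
        with pytest.raises(ValueError):
            fit_pdd_exponential(d, y)
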