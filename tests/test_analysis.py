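"""Profile reduction, region partition, strain and scaling fits."""

import numpy as np
import pytest

from dpdgel import analysis
from dpdgel.analysis import (ProfileSet, density_profile, fit_scaling,
                             friction_curves, partition_regions,
                             region_densities, shear_strain,
                             velocity_profile)
from dpdgel.shear import FrictionRecord


BOX = (5.0, 5.0, 10.0)


def frames_uniform(n=2000, frames=4, seed=0, zmax=10.0):
    rng = np.random.default_rng(seed)
    return [np.column_stack([rng.random(n) * 5, rng.random(n) * 5,
                             rng.random(n) * zmax]) for _ in range(frames)]


class TestDensityProfile:
    def test_uniform_gas_flat_at_unity(self):
        # 2000 beads in 5x5x10 at rho0 = 8 -> rho/rho0 = 1
        prof = density_profile(frames_uniform(), None, BOX, rho0=8.0,
                               nbins=10)
        np.testing.assert_allclose(prof.value, 1.0, atol=0.12)

    def test_slab_step_profile_counts_conserved(self):
        frames = frames_uniform(zmax=5.0)
        prof = density_profile(frames, None, BOX, rho0=8.0, nbins=20)
        # integral of unnormalized density * area = bead count
        total = prof.value.sum() * 8.0 * prof.bin_width * 25.0
        assert total == pytest.approx(2000, rel=1e-9)
        assert prof.value[:10].mean() > 10 * prof.value[10:].mean()

    def test_empty_range_raises(self):
        with pytest.raises(ValueError):
            density_profile(frames_uniform(), None, BOX, nbins=0)


class TestVelocityProfile:
    def test_uniform_streaming_flat_at_one(self):
        frames = frames_uniform(frames=2)
        vels = [np.column_stack([np.full(2000, 0.3), np.zeros(2000),
                                 np.zeros(2000)])] * 2
        prof = velocity_profile(frames, vels, None, BOX, V=0.3, nbins=10)
        np.testing.assert_allclose(prof.value, 1.0, atol=1e-9)

    def test_v_zero_returns_unnormalized(self):
        frames = frames_uniform(frames=1)
        vels = [np.zeros((2000, 3))]
        prof = velocity_profile(frames, vels, None, BOX, V=0.0)
        assert prof.normalization == 1.0


def synthetic_profile(z_t=6.4, plateau=1.0, zmax=16.0, nbins=80, xi0=3.2):
    z = (np.arange(nbins) + 0.5) * zmax / nbins
    rho = np.where(z < z_t, plateau * z / z_t, plateau)
    rho[z > 0.85 * zmax] = 0.0
    return ProfileSet(z, rho, np.ones(nbins), zmax / nbins, "density", 3.0)


class TestPartitionRegions:
    def test_sharp_step_edge_detected(self):
        xi0 = 3.2
        nbins = 100
        z = (np.arange(nbins) + 0.5) * 0.16
        rho = np.where(z >= 2 * xi0, 1.0, 0.0)
        rho[z > 14.0] = 0.0
        prof = ProfileSet(z, rho, np.ones(nbins), 0.16, "density", 3.0)
        part = partition_regions(prof, xi0)
        assert part.z_t == pytest.approx(2 * xi0, abs=0.2)

    def test_threshold_sensitivity_small_on_smooth_profile(self):
        prof = synthetic_profile()
        p95 = partition_regions(prof, 3.2, plateau_threshold=0.95)
        p90 = partition_regions(prof, 3.2, plateau_threshold=0.90)
        assert abs(p95.z_t - p90.z_t) < 0.3 * 3.2

    def test_thin_gel_raises(self):
        prof = synthetic_profile(zmax=8.0, nbins=40)
        with pytest.raises(ValueError, match="thinner"):
            partition_regions(prof, 3.2)


class TestRegionDensities:
    def test_uniform_profile_equal_regions(self):
        nbins = 80
        z = (np.arange(nbins) + 0.5) * 0.2
        prof = ProfileSet(z, np.ones(nbins), np.ones(nbins), 0.2,
                          "density", 3.0)
        from dpdgel.analysis import RegionPartition

        part = RegionPartition(3.2, 0.96, 6.4, 16.0)
        rb, ri = region_densities(prof, part)
        assert rb == pytest.approx(ri)


class TestShearStrain:
    def test_affine_displacement_recovered(self, rng):
        z = rng.random(500) * 8.0
        g = 0.37
        disp = g * z + 0.05 * rng.standard_normal(500)
        assert shear_strain(disp, z) == pytest.approx(g, abs=0.01)

    def test_pure_noise_gives_zero(self, rng):
        z = rng.random(800) * 8.0
        disp = 0.3 * rng.standard_normal(800)
        assert abs(shear_strain(disp, z)) < 0.02

    def test_rigid_drift_removed(self, rng):
        z = rng.random(300) * 8.0
        disp = 5.0 + 0.2 * z
        assert shear_strain(disp, z,
                            drift_ids=np.arange(10)) == pytest.approx(0.2)

    def test_mismatched_reference_raises(self):
        with pytest.raises(ValueError):
            shear_strain(np.ones(5), np.ones(4))


def record(Wi, P, mu, err=0.01, seed=0):
    return FrictionRecord(np.arange(3), np.full(3, mu), np.full(3, 5.0),
                          1.0, 0.1, P, Wi, seed, mu=mu, mu_err=err)


class TestFrictionCurves:
    def test_identical_mu_normalizes_to_one(self):
        recs = [record(w, 0.14, 0.5) for w in (1e-3, 1e-2, 0.1, 1.0)]
        df = friction_curves(recs)
        low = df[df.Wi < analysis.MU0_WI_WINDOW]
        assert len(low) == 1
        np.testing.assert_allclose(df.mu_norm, 1.0)

    def test_missing_low_wi_warns(self):
        recs = [record(w, 0.14, 0.5) for w in (0.1, 1.0)]
        with pytest.warns(UserWarning, match="normalization skipped"):
            df = friction_curves(recs)
        assert df.mu_norm.isna().all()


class TestFitScaling:
    def test_exact_linear_slope(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        fit = fit_scaling(x, 3.0 * x, kind="linear")
        assert fit.slope == pytest.approx(3.0)
        assert fit.slope_err == pytest.approx(0.0, abs=1e-10)

    def test_exact_power_law_exponent(self):
        x = np.array([0.14, 0.21, 0.28])
        fit = fit_scaling(x, x ** -0.77, kind="power")
        assert fit.slope == pytest.approx(-0.77, abs=1e-9)

    def test_noisy_power_law_recovery(self, rng):
        """Exponent of a noisy synthetic power law recovered within 2 SE."""
        x = np.logspace(-1, 0.5, 20)
        y = 2.0 * x ** -0.77 * np.exp(0.05 * rng.standard_normal(20))
        fit = fit_scaling(x, y, kind="power")
        assert abs(fit.slope + 0.77) < 2.5 * max(fit.slope_err, 0.01)

    def test_bootstrap_error_comparable(self, rng):
        x = np.linspace(1, 5, 15)
        y = 2.0 + 0.5 * x + 0.2 * rng.standard_normal(15)
        f1 = fit_scaling(x, y, kind="linear")
        f2 = fit_scaling(x, y, kind="linear", n_boot=400, seed=1)
        assert f2.slope == pytest.approx(f1.slope)
        assert 0.2 < f2.slope_err / max(f1.slope_err, 1e-9) < 5.0

    def test_nonpositive_power_data_raises(self):
        with pytest.raises(ValueError):
            fit_scaling([1, 2, 3], [1.0, -1.0, 2.0], kind="power")

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_scaling([1, 2], [1, 2])

    def test_prediction_roundtrip(self):
        x = np.array([0.5, 1.0, 2.0, 4.0])
        fit = fit_scaling(x, 3.0 * x ** 1.5, kind="power")
        np.testing.assert_allclose(fit.predict(x), 3.0 * x ** 1.5,
                                   rtol=1e-8)
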