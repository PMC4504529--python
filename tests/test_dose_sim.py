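"""Noise insertion and water-phantom calibration.

The oracle throughout is the direct acquisition: a simulated dose reduction
to fraction alpha must be statistically indistinguishable (per-ray SD, ray
values, reconstructed ROI noise) from a true scan at alpha times the tube
current.
"""

import numpy as np
import pytest
import scipy.stats

import ldctsim as L


@pytest.fixture(scope="module")
def small_water():
    return L.make_water_phantom(grid_size=128)


@pytest.fixture(scope="module")
def flat_scan():
    """A measured flat sinogram of many independent identical rays."""
    sino = L.Sinogram(np.full((1, 30000), 2.0), 1.0)
    protocol = L.ScanProtocol(eff_mas=50.0, sigma_e=10.0)
    return L.measure(sino, protocol, seed=11)


class TestInsertNoiseContracts:
    def test_alpha_one_is_identity(self, water_sino, protocol):
        scan = L.measure(water_sino, protocol, seed=0)
        out = L.insert_noise(scan, L.NoiseModel(alpha=1.0), seed=1)
        assert np.array_equal(out.values, scan.values)

    @pytest.mark.parametrize("alpha", [1.5, 0.0, -0.2])
    def test_dose_increase_rejected(self, alpha):
        with pytest.raises(ValueError):
            L.NoiseModel(alpha=alpha)

    def test_protocol_required(self):
        bare = L.Sinogram(np.zeros((2, 4)), 1.0)
        with pytest.raises(ValueError):
            L.insert_noise(bare, L.NoiseModel(alpha=0.5), seed=0)

    def test_output_protocol_scaled(self, flat_scan):
        out = L.insert_noise(flat_scan, L.NoiseModel(alpha=0.25), seed=0)
        assert out.protocol.eff_mas == pytest.approx(12.5)
        assert out.meta["alpha"] == 0.25

    def test_same_seed_bit_identical(self, flat_scan):
        model = L.NoiseModel(alpha=0.5)
        a = L.insert_noise(flat_scan, model, seed=3)
        b = L.insert_noise(flat_scan, model, seed=3)
        assert np.array_equal(a.values, b.values)

    def test_thinning_rejects_calibration_factor(self, flat_scan):
        model = L.NoiseModel(alpha=0.5, calib_factor=1.2)
        with pytest.raises(ValueError):
            L.insert_noise(flat_scan, model, seed=0, mode="poisson")

    def test_unbiased_per_ray(self):
        # mean of p' over 500 realizations stays on p_hat (3 MC-SE bands)
        sino = L.Sinogram(np.full((1, 200), 2.0), 1.0)
        scan = L.measure(sino, L.ScanProtocol(eff_mas=50.0), seed=2)
        model = L.NoiseModel(alpha=0.25)
        reps = np.stack(
            [L.insert_noise(scan, model, seed=s).values[0] for s in range(500)]
        )
        se = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        z = (reps.mean(axis=0) - scan.values[0]) / se
        assert np.mean(np.abs(z) > 3.0) < 0.01


class TestDirectAcquisitionOracle:
    """insert_noise at alpha must match acquire at alpha * N0."""

    @pytest.mark.parametrize("mode", ["gaussian", "poisson"])
    @pytest.mark.parametrize("alpha", [0.5, 0.25])
    def test_pooled_ray_sd_and_location(self, flat_scan, mode, alpha):
        model = L.NoiseModel(alpha=alpha)
        sim = L.insert_noise(flat_scan, model, seed=21, mode=mode)
        clean = L.Sinogram(np.full((1, 30000), 2.0), 1.0)
        direct = L.measure(
            clean, L.ScanProtocol(eff_mas=50.0 * alpha, sigma_e=10.0), seed=22
        )
        assert sim.values.std() == pytest.approx(direct.values.std(), rel=0.05)
        # independent two-sample location check on the pooled rays
        p = scipy.stats.mannwhitneyu(sim.values.ravel(), direct.values.ravel()).pvalue
        assert p > 0.01

    def test_quarter_dose_doubles_recon_noise(self, water_sino, central_roi):
        protocol = L.ScanProtocol(eff_mas=200.0, sigma_e=0.0)
        ratios = []
        for s in range(5):
            full = L.measure(water_sino, protocol, seed=100 + s)
            low = L.insert_noise(full, L.NoiseModel(alpha=0.25), seed=200 + s)
            ratios.append(
                L.roi_stats(L.fbp(low), central_roi).sd
                / L.roi_stats(L.fbp(full), central_roi).sd
            )
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_composition_consistency(self, flat_scan):
        # alpha1 then alpha2/alpha1 must equal single-step alpha2
        two_step = L.insert_noise(
            L.insert_noise(flat_scan, L.NoiseModel(alpha=0.75), seed=31),
            L.NoiseModel(alpha=0.5 / 0.75),
            seed=32,
        )
        one_step = L.insert_noise(flat_scan, L.NoiseModel(alpha=0.5), seed=33)
        assert two_step.protocol.eff_mas == pytest.approx(25.0)
        assert two_step.values.std() == pytest.approx(one_step.values.std(), rel=0.05)

    def test_monotone_noise_in_alpha(self, flat_scan):
        sds = [
            L.insert_noise(flat_scan, L.NoiseModel(alpha=a), seed=41).values.std()
            for a in (1.0, 0.75, 0.5, 0.25)
        ]
        assert sds == sorted(sds)


class TestElectronicNoiseRegime:
    def test_excess_over_pure_quantum_at_ultra_low_dose(self, water_sino, central_roi):
        alpha = 0.0625
        sds = {}
        for sigma_e in (0.0, 10.0):
            protocol = L.ScanProtocol(eff_mas=160.0, sigma_e=sigma_e)
            full = np.mean(
                [
                    L.roi_stats(L.fbp(L.measure(water_sino, protocol, s)), central_roi).sd
                    for s in (0, 1, 2, 3)
                ]
            )
            low = np.mean(
                [
                    L.roi_stats(
                        L.fbp(
                            L.measure(
                                water_sino, protocol.at_dose_fraction(alpha), 10 + s
                            )
                        ),
                        central_roi,
                    ).sd
                    for s in (0, 1, 2, 3)
                ]
            )
            sds[sigma_e] = (full, low)
        # sigma_e = 0: the inverse-square-root law holds
        full, low = sds[0.0]
        assert low / full == pytest.approx(1.0 / np.sqrt(alpha), rel=0.05)
        # sigma_e > 0: electronic noise lifts the ultra-low-dose SD above it
        full, low = sds[10.0]
        assert low / full > 1.05 / np.sqrt(alpha)


class TestCalibration:
    recon_kw = dict(recon_grid=128)

    def test_predicted_ratio_is_inverse_sqrt_alpha_without_electronic_noise(
        self, water_sino
    ):
        protocol = L.ScanProtocol(eff_mas=200.0, sigma_e=0.0)
        r = L.predicted_sd_ratio(water_sino, protocol, 0.0625, 25.0)
        assert r == pytest.approx(4.0, abs=1e-12)

    def test_exact_model_is_a_fixed_point(self, small_water):
        protocol = L.ScanProtocol(eff_mas=200.0, sigma_e=0.0)
        res = L.calibrate(
            L.NoiseModel(alpha=0.0625), small_water, protocol, seed=3, **self.recon_kw
        )
        assert res.converged
        assert abs(res.model.calib_factor - 1.0) < 0.05
        # sigma_e = 0 target: four times the full-dose ROI noise
        assert res.target_sd == pytest.approx(4.0 * res.full_dose_sd)

    def test_misscaled_variance_recovers_target(self, small_water):
        protocol = L.ScanProtocol(eff_mas=200.0)
        res = L.calibrate(
            L.NoiseModel(alpha=0.0625, calib_factor=4.0),
            small_water,
            protocol,
            seed=5,
            **self.recon_kw,
        )
        assert res.converged and res.n_iter <= 20
        assert res.residual <= 0.01

    def test_no_convergence_raises_with_residual(self, small_water):
        protocol = L.ScanProtocol(eff_mas=200.0)
        with pytest.raises(L.CalibrationError, match="residual"):
            L.calibrate(
                L.NoiseModel(alpha=0.0625, calib_factor=4.0),
                small_water,
                protocol,
                seed=5,
                tol=1e-9,
                max_iter=1,
                n_realizations=2,
                n_base=2,
                **self.recon_kw,
            )

    def test_invalid_target_alpha(self, small_water):
        with pytest.raises(ValueError):
            L.calibrate(
                L.NoiseModel(alpha=0.5),
                small_water,
                L.ScanProtocol(eff_mas=200.0),
                target_alpha=1.5,
            )
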