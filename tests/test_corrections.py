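"""Beam-output and beam-symmetry corrections."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

import epidcal as ec


class TestOutputFactor:
    def test_identical_flat_lines_give_unity(self):
        line = np.full(46, 500.0)
        for sign in (1, -1):
            assert ec.output_factor(line, line, sign) == pytest.approx(
                1.0, abs=1e-14
            )

    def test_flat_scale_is_inverted(self):
        line = np.full(46, 500.0)
        for sign in (1, -1):
            f = ec.output_factor(line, 1.002 * line, sign)
            assert f == pytest.approx(1 / 1.002, rel=1e-12)

    def test_unperturbed_symmetric_gains_give_unity(self, beam,
                                                    symmetric_gains):
        # with symmetric gains and no drift the window products match
        aset = ec.simulate_calibration_set(beam, symmetric_gains,
                                           ec.PerturbationSpec.none())
        _, factors = ec.apply_output_corrections(aset)
        for f in factors.values():
            assert f == pytest.approx(1.0, abs=1e-12)

    def test_recovers_injected_drift_on_symmetric_gains(self, beam,
                                                        symmetric_gains):
        scales = {"B": 1.002, "C": 0.9985, "D": 1.0013, "E": 0.999}
        pert = ec.PerturbationSpec(output_scales=scales, noise_sigma=0.0)
        aset = ec.simulate_calibration_set(beam, symmetric_gains, pert)
        _, factors = ec.apply_output_corrections(aset)
        for label, s in scales.items():
            assert abs(factors[label] * s - 1.0) < 1e-6

    def test_nondefault_window_warns(self):
        line = np.full(46, 500.0)
        with pytest.warns(UserWarning, match="window"):
            ec.output_factor(line, line, 1, k=10)

    def test_window_exceeding_profile_rejected(self):
        line = np.full(10, 500.0)
        with pytest.raises(ec.ConfigError):
            with pytest.warns(UserWarning):
                ec.output_factor(line, line, 1, k=8)


class TestApplyOutputCorrection:
    def test_unit_factor_is_identity(self, noiseless_set):
        img = noiseless_set["B"]
        out = ec.apply_output_correction(img, 1.0)
        assert np.array_equal(out.counts, img.counts)

    def test_factor_multiplies_counts(self, noiseless_set):
        img = noiseless_set["B"]
        out = ec.apply_output_correction(img, 2.0)
        assert np.array_equal(out.counts, 2.0 * img.counts)
        assert out.meta["output_factor_applied"] == 2.0

    def test_round_trip(self, noiseless_set):
        img = noiseless_set["B"]
        back = ec.apply_output_correction(
            ec.apply_output_correction(img, 1.002), 1 / 1.002
        )
        assert np.allclose(back.counts, img.counts, rtol=1e-15)


class TestDriftPropagation:
    def test_uncorrected_error_grows_with_chain_distance(self, beam,
                                                         symmetric_gains):
        # a constant per-acquisition scale error is systematic: the chain
        # multiplies it in at every step, so the gain error must grow
        # monotonically with distance from the reference pixel
        pert = ec.PerturbationSpec(
            output_scales={"B": 1.002, "C": 0.998, "D": 1.0015, "E": 0.9985},
            noise_sigma=0.0,
        )
        aset = ec.simulate_calibration_set(beam, symmetric_gains, pert)
        res = ec.compute_psm(aset, output_correction=False)
        err = np.abs(res.psm_mean.values / symmetric_gains.values - 1.0)
        rr, cc = np.meshgrid(np.arange(46), np.arange(46), indexing="ij")
        dist = np.abs(rr - 23) + np.abs(cc - 23)
        mean_by_dist = [err[dist == d].mean() for d in range(1, dist.max())]
        rho = spearmanr(np.arange(len(mean_by_dist)), mean_by_dist).statistic
        assert rho > 0.95
        assert err.max() > 0.01  # percent-level error from 0.2% drift

        corrected = ec.compute_psm(aset, output_correction=True)
        err_c = np.abs(corrected.psm_mean.values / symmetric_gains.values - 1)
        assert err_c.max() < 1e-3  # below 0.1% once f is applied


class TestFitSymmetryU:
    def test_zero_profile_fits_zero(self):
        assert ec.fit_symmetry_u(np.zeros(40), 46.0) == 0.0

    def test_pure_basis_recovered_exactly(self):
        y = np.arange(40) - 19.5
        profile = 0.0015 * np.sin(np.pi * y / 46.0)
        u = ec.fit_symmetry_u(profile, 46.0, y)
        assert u == pytest.approx(0.0015, abs=1e-15)

    @given(st.floats(-0.01, 0.01), st.floats(-0.01, 0.01),
           st.integers(0, 2 ** 31 - 1))
    def test_fit_is_linear_in_profile(self, a, b, seed):
        rng = np.random.default_rng(seed)
        d1 = rng.normal(0, 1e-3, 40)
        d2 = rng.normal(0, 1e-3, 40)
        u1 = ec.fit_symmetry_u(d1, 46.0)
        u2 = ec.fit_symmetry_u(d2, 46.0)
        u12 = ec.fit_symmetry_u(a * d1 + b * d2, 46.0)
        assert u12 == pytest.approx(a * u1 + b * u2, abs=1e-12)

    def test_matches_grid_search_under_noise(self):
        # independent oracle: dense grid search over the amplitude
        rng = np.random.default_rng(12)
        y = np.arange(40) - 19.5
        s = np.sin(np.pi * y / 46.0)
        truth = 0.0015
        profile = truth * s + rng.normal(0, 1e-4, 40)
        u = ec.fit_symmetry_u(profile, 46.0, y)
        grid = np.linspace(-0.005, 0.005, 20001)
        sse = ((profile[None, :] - grid[:, None] * s[None, :]) ** 2).sum(axis=1)
        u_grid = grid[np.argmin(sse)]
        assert u == pytest.approx(u_grid, abs=5e-7)  # grid resolution
        se = 1e-4 / np.sqrt((s ** 2).sum())
        assert abs(u - truth) < 3 * se

    def test_degenerate_basis_rejected(self):
        with pytest.raises(ec.ConfigError):
            ec.fit_symmetry_u(np.ones(5), 1e30, np.zeros(5))


class TestSymmetryLoop:
    def test_unperturbed_set_converges_immediately(self, noiseless_set):
        loop = ec.symmetry_loop(noiseless_set)
        assert loop.converged
        assert loop.iterations == 1
        for corr in loop.corrections.values():
            assert abs(corr.u) < 1e-10

    def test_recovers_injected_tilt_on_one_acquisition(self, beam,
                                                       symmetric_gains):
        truth_u = 0.0015
        pert = ec.PerturbationSpec(symmetry_u={"D": truth_u}, noise_sigma=0.0)
        aset = ec.simulate_calibration_set(beam, symmetric_gains, pert)
        aset, _ = ec.apply_output_corrections(aset)
        loop = ec.symmetry_loop(aset)
        assert loop.converged
        assert loop.corrections["D"].u == pytest.approx(truth_u, rel=0.10)
        # the unperturbed acquisitions stay (nearly) uncorrected
        for label in ("B", "C", "E"):
            assert abs(loop.corrections[label].u) < 0.1 * truth_u

    def test_correction_shrinks_psm_error(self, beam, symmetric_gains):
        g = symmetric_gains.values
        pert = ec.PerturbationSpec(symmetry_u={"D": 0.0015}, noise_sigma=0.0)
        aset = ec.simulate_calibration_set(beam, symmetric_gains, pert)
        before = ec.compute_psm(aset, output_correction=True)
        rms_before = np.sqrt(np.mean((before.psm_mean.values - g) ** 2))
        corrected_input, _ = ec.apply_output_corrections(aset)
        loop = ec.symmetry_loop(corrected_input)
        rms_after = np.sqrt(
            np.mean((loop.calibration.psm_mean.values - g) ** 2)
        )
        assert rms_after <= 0.5 * rms_before

    def test_nonconvergence_is_flagged(self, beam, symmetric_gains):
        pert = ec.PerturbationSpec(symmetry_u={"D": 0.0015}, noise_sigma=0.0)
        aset = ec.simulate_calibration_set(beam, symmetric_gains, pert)
        aset, _ = ec.apply_output_corrections(aset)
        with pytest.warns(UserWarning, match="did not converge"):
            loop = ec.symmetry_loop(aset, max_iter=1)
        assert not loop.converged
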