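"""Intercalibration chains: 1D recursions, 2D orderings, averaging."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import epidcal as ec
from epidcal.core import ShiftPlan
from epidcal.intercalib import ordering_label

positive_lines = st.lists(
    st.floats(0.5, 2.0), min_size=12, max_size=12
).map(np.array)


def brute_force_chain(central, shifted, sign, ref, ref_value=1.0):
    """Independent oracle: sequential application of the single-step gain
    relation, coded separately from the implementation."""
    n = len(central)
    g = [None] * n
    g[ref] = ref_value
    for t in range(ref, n - 1):
        if sign == 1:
            g[t + 1] = shifted[t] / central[t + 1] * g[t]
        else:
            g[t + 1] = central[t] / shifted[t + 1] * g[t]
    for t in range(ref, 0, -1):
        if sign == 1:
            g[t - 1] = central[t] / shifted[t - 1] * g[t]
        else:
            g[t - 1] = shifted[t] / central[t - 1] * g[t]
    return np.array(g)


class TestChain1D:
    def test_constant_lines_give_unit_gains(self):
        line = np.full(10, 123.4)
        g = ec.chain_gains_1d(line, line, 1, 5)
        assert np.allclose(g, 1.0, atol=1e-15)

    def test_single_step_identity_case(self):
        # equal counts at the matched pair of cells force a unit gain at
        # the reference pixel's neighbour
        central = np.array([10.0, 20.0, 30.0, 40.0])
        shifted = np.array([30.0, 11.0, 13.0, 17.0])
        g = ec.chain_gains_1d(central, shifted, 1, 2)
        assert g[2] == 1.0
        assert g[3] == shifted[2] / central[3]

    def test_six_pixel_toy_recovers_truth(self):
        # truth gains and a ramp fluence; counts built from the fluence
        # relation C = F / g, recovery checked against g / g[ref]
        g_true = np.array([1.00, 1.10, 0.90, 1.05, 0.95, 1.02])
        fluence = np.array([100.0, 110.0, 120.0, 130.0, 140.0, 150.0])
        ref = 2
        central = fluence / g_true
        shifted_b = np.empty(6)
        shifted_b[:-1] = fluence[1:] / g_true[:-1]  # pixel t sees cell t+1
        shifted_b[-1] = 160.0 / g_true[-1]          # cell beyond the grid
        rec = ec.chain_gains_1d(central, shifted_b, 1, ref)
        assert np.allclose(rec, g_true / g_true[ref], rtol=1e-13)
        closed = ec.chain_gains_1d_closed_form(central, shifted_b, 1, ref)
        assert np.allclose(closed, rec, rtol=1e-13)

    @given(positive_lines, positive_lines, st.sampled_from([1, -1]),
           st.integers(0, 11))
    def test_closed_form_equals_recursion(self, central, shifted, sign, ref):
        rec = ec.chain_gains_1d(central, shifted, sign, ref)
        closed = ec.chain_gains_1d_closed_form(central, shifted, sign, ref)
        oracle = brute_force_chain(central, shifted, sign, ref)
        assert np.allclose(closed, rec, rtol=1e-12, atol=0)
        assert np.allclose(rec, oracle, rtol=1e-12, atol=0)

    def test_nonpositive_count_names_index(self):
        line = np.ones(8)
        bad = line.copy()
        bad[5] = -1.0
        with pytest.raises(ec.DataError, match="index 5"):
            ec.chain_gains_1d(line, bad, 1, 3)

    def test_count_floor_aborts_with_diagnostic(self):
        line = np.full(12, 1000.0)
        low = line.copy()
        low[9] = 1.0  # far below 1% of the median
        with pytest.raises(ec.DataError, match="median"):
            ec.chain_gains_1d(line, low, 1, 5)


class TestChain2D:
    @pytest.mark.parametrize("h,v,order", [
        ("B", "D", "HV"), ("B", "D", "VH"), ("B", "E", "HV"), ("B", "E", "VH"),
        ("C", "D", "HV"), ("C", "D", "VH"), ("C", "E", "HV"), ("C", "E", "VH"),
    ])
    def test_noiseless_recovery_every_ordering(self, noiseless_set,
                                               truth_gains, h, v, order):
        psm = ec.chain_pms_2d(noiseless_set, h, v, order)
        err = np.abs(psm.values / truth_gains.values - 1.0)
        assert err.max() < 1e-10

    def test_flat_beam_unit_gains_give_unit_map(self):
        beam = ec.BeamModel(field_width=500.0, radial_coeffs=(0.0, 0.0),
                            background=0.0)
        g = ec.GainMap(np.ones((20, 20)), (10, 10))
        aset = ec.simulate_calibration_set(beam, g, ec.PerturbationSpec.none())
        psm = ec.chain_pms_2d(aset, "B", "D", "HV")
        assert np.allclose(psm.values, 1.0, atol=1e-10)

    def test_missing_acquisition_rejected(self, noiseless_set):
        images = {l: noiseless_set[l]
                  for l in ("A", "B", "D")}
        plan = ec.three_acquisition_plan()
        aset = ec.AcquisitionSet(images, plan)
        with pytest.raises(ec.ConfigError):
            ec.chain_pms_2d(aset, "C", "D", "HV")

    def test_grid_flip_symmetry(self, beam, truth_gains):
        # flipping the truth upside town and exchanging the +y/-y
        # acquisitions must flip the recovered PSM identically
        flipped_gains = ec.GainMap(truth_gains.values[::-1].copy(), (22, 23))
        none = ec.PerturbationSpec.none()
        aset = ec.simulate_calibration_set(beam, truth_gains, none)
        psm = ec.chain_pms_2d(aset, "B", "D", "HV").values
        flipped_set = ec.simulate_calibration_set(beam, flipped_gains, none)
        psm_f = ec.chain_pms_2d(flipped_set, "B", "E", "HV",
                                ref=(22, 23)).values
        ratio = psm_f[::-1] / psm
        assert np.allclose(ratio, ratio[23, 23], rtol=1e-10)


class TestOrderings:
    def test_standard_plan_yields_eight(self):
        triples = ec.enumerate_orderings(ec.default_plan())
        assert len(triples) == 8
        assert ("B", "D", "HV") in triples
        assert ("B", "D", "VH") in triples
        labels = [ordering_label(*t) for t in triples]
        assert labels == ["BD", "DB", "BE", "EB", "CD", "DC", "CE", "EC"]

    def test_three_acquisition_plan_yields_two(self):
        triples = ec.enumerate_orderings(ec.three_acquisition_plan())
        assert triples == [("B", "D", "HV"), ("B", "D", "VH")]

    def test_plan_without_vertical_shift_rejected(self):
        plan = ShiftPlan(("A", "B"), {"A": (0, 0), "B": (1, 0)})
        with pytest.raises(ec.ConfigError):
            ec.enumerate_orderings(plan)


class TestComputePSM:
    def test_noiseless_sets_agree_to_machine_precision(self, noiseless_set):
        res = ec.compute_psm(noiseless_set, output_correction=False)
        assert res.n_sets == 8
        assert res.psm_std.max() < 1e-12

    def test_mean_is_one_at_reference(self, noiseless_set):
        res = ec.compute_psm(noiseless_set, output_correction=False)
        assert res.psm_mean.values[23, 23] == 1.0

    def test_residuals_sum_to_zero_per_pixel(self, beam, truth_gains):
        pert = ec.PerturbationSpec(noise_sigma=0.001, seed=6)
        aset = ec.simulate_calibration_set(beam, truth_gains, pert)
        res = ec.compute_psm(aset, output_correction=False)
        assert np.abs(res.residuals.sum(axis=0)).max() < 1e-12

    def test_noisy_spread_grows_with_chain_distance(self, beam, truth_gains):
        # count noise accumulates along the chains, so the spread over the
        # eight sets must increase away from the reference pixel
        from scipy.stats import spearmanr

        pert = ec.PerturbationSpec(noise_sigma=0.001, seed=3)
        aset = ec.simulate_calibration_set(beam, truth_gains, pert)
        res = ec.compute_psm(aset, output_correction=False)
        rr, cc = np.meshgrid(np.arange(46), np.arange(46), indexing="ij")
        dist = np.abs(rr - 23) + np.abs(cc - 23)
        rho = spearmanr(dist.ravel(), res.psm_std.ravel()).statistic
        assert rho > 0.5

    def test_three_acquisition_set_yields_two_psms(self, noiseless_set):
        plan = ec.three_acquisition_plan()
        images = {l: noiseless_set[l] for l in plan.labels}
        aset = ec.AcquisitionSet(images, plan, noiseless_set.truth)
        res = ec.compute_psm(aset, output_correction=False)
        assert res.n_sets == 2
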