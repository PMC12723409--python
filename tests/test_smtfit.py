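import numpy as np
import pytest

from axonsf import (DiameterMap, DWIDataset, PowderSignal, diameter_from_Dperp,
                    effective_Dperp, fit_dti_principal_diffusivity, fit_smt,
                    powder_average, roi_diameter_distribution,
                    smt_powder_signal, uniform_directions)
from axonsf.morphometry import EmptyDistributionError
from axonsf.smtfit import R_MAX_UM, FitError, InvalidVoxelError

D0 = 0.45


def _dataset_from_shell_values(values_per_shell, n_b0=9, n_dirs=30):
    """1-voxel dataset with a constant value across each shell's directions."""
    dirs = uniform_directions(n_dirs)
    bvals = np.concatenate([np.zeros(n_b0),
                            np.repeat([24450.0, 21247.0, 17560.0], n_dirs)])
    bvecs = np.vstack([np.zeros((n_b0, 3))] + [dirs] * 3)
    sig = np.concatenate([np.ones(n_b0),
                          np.repeat(values_per_shell, n_dirs)])
    return DWIDataset(volume=sig[None, None, None, :], bvals=bvals, bvecs=bvecs)


class TestPowderAverage:
    def test_constant_shell_signal_passes_through(self):
        ds = _dataset_from_shell_values([0.3, 0.4, 0.5])
        ps = powder_average(ds, (0, 0, 0))
        # shells come back sorted ascending in b
        np.testing.assert_allclose(ps.b_shells, [17560.0, 21247.0, 24450.0])
        np.testing.assert_allclose(ps.sbar, [0.5, 0.4, 0.3], rtol=1e-12)
        assert list(ps.n_dirs) == [30, 30, 30]

    def test_matches_closed_form_for_model_signals(self, protocol):
        b = [24450.0, 21247.0, 17560.0]
        vals = smt_powder_signal(np.array(b), 0.7, D0, 0.03)
        ps = powder_average(_dataset_from_shell_values(vals), (0, 0, 0))
        expected = smt_powder_signal(ps.b_shells, 0.7, D0, 0.03)
        np.testing.assert_allclose(ps.sbar, expected, atol=1e-6)

    def test_zero_b0_marks_voxel_invalid(self):
        ds = _dataset_from_shell_values([0.3, 0.4, 0.5])
        ds.volume[..., :9] = 0.0
        with pytest.raises(InvalidVoxelError):
            powder_average(ds, (0, 0, 0))

    def test_corrupt_powder_value_rejected(self):
        with pytest.raises(InvalidVoxelError):
            PowderSignal([17560, 21247, 24450], [0.5, 0.4, 1.8], [30] * 3)


class TestDTIPrincipalDiffusivity:
    def _signals(self, eigvals_um2_ms, n_dirs=61, b=4000.0):
        dirs = uniform_directions(n_dirs)
        bvals = np.concatenate([[0.0], np.full(n_dirs, b)])
        bvecs = np.vstack([np.zeros(3), dirs])
        D = np.diag(np.asarray(eigvals_um2_ms) * 1e-3)  # mm²/s
        adc = np.einsum("ni,ij,nj->n", bvecs, D, bvecs)
        return np.exp(-bvals * adc), bvecs, bvals

    def test_recovers_prolate_tensor_principal_eigenvalue(self):
        s, bvecs, bvals = self._signals([1.7, 0.3, 0.3])
        d0 = fit_dti_principal_diffusivity(s, bvecs, bvals)
        assert d0 == pytest.approx(1.7, abs=1e-6)

    def test_isotropic_tensor_returns_its_diffusivity(self):
        s, bvecs, bvals = self._signals([0.8, 0.8, 0.8])
        assert fit_dti_principal_diffusivity(s, bvecs, bvals) == pytest.approx(0.8, abs=1e-6)

    def test_roi_average_over_voxels(self):
        s1, bvecs, bvals = self._signals([1.6, 0.3, 0.3])
        s2, _, _ = self._signals([1.8, 0.3, 0.3])
        d0 = fit_dti_principal_diffusivity(np.vstack([s1, s2]), bvecs, bvals)
        assert d0 == pytest.approx(1.7, abs=1e-6)

    def test_underdetermined_design_rejected(self):
        s, bvecs, bvals = self._signals([1.7, 0.3, 0.3], n_dirs=5)
        with pytest.raises(FitError):
            fit_dti_principal_diffusivity(s, bvecs, bvals)


class TestFitSMT:
    def test_noiseless_recovery(self, protocol):
        b = protocol.bvalues
        ps = PowderSignal(b, smt_powder_signal(b, 0.7, D0, 0.05), [30] * 3)
        fit = fit_smt(ps, protocol, D0)
        assert fit.converged
        assert fit.va == pytest.approx(0.7, rel=1e-3)
        assert fit.Dperp == pytest.approx(0.05, rel=1e-3)

    def test_isotropic_signals_push_dperp_to_upper_bound(self, protocol):
        b = protocol.bvalues
        ps = PowderSignal(b, 0.8 * np.exp(-b * D0 * 1e-3), [30] * 3)
        fit = fit_smt(ps, protocol, D0)
        # the isotropic corner is a shallow ridge (va and D⊥ trade off at
        # second order in b(D0−D⊥)), so the bound is reached only to ~1%
        assert fit.Dperp == pytest.approx(D0, rel=0.01)
        assert fit.residual_norm < 1e-6

    def test_single_shell_rejected(self, protocol):
        ps = PowderSignal([24450.0], [0.1], [30])
        with pytest.raises(FitError):
            fit_smt(ps, protocol, D0)


class TestDiameterInversion:
    def test_zero_maps_to_zero(self, protocol):
        assert diameter_from_Dperp(0.0, protocol, D0) == 0.0

    @pytest.mark.parametrize("d", [2.0, 4.0, 6.0])
    def test_round_trip(self, protocol, d):
        dperp = effective_Dperp(d / 2, protocol.delta, protocol.Delta, D0)
        assert diameter_from_Dperp(float(dperp), protocol, D0) == pytest.approx(d, abs=1e-6)

    def test_weak_quarter_power_dependence_on_d0(self, protocol):
        # d ∝ D0^(1/4): doubling D0 scales the inverted diameter by ~2^(1/4)
        dperp = float(effective_Dperp(2.0, protocol.delta, protocol.Delta, D0))
        d_lo = diameter_from_Dperp(dperp, protocol, D0)
        d_hi = diameter_from_Dperp(dperp, protocol, 2 * D0)
        assert 1.14 <= d_hi / d_lo <= 1.25

    def test_unreachable_dperp_is_capped_and_flagged(self, protocol):
        sup = float(effective_Dperp(R_MAX_UM, protocol.delta, protocol.Delta, D0))
        d, capped = diameter_from_Dperp(sup * 1.01, protocol, D0, full_output=True)
        assert capped and d == 2 * R_MAX_UM


class TestROIDistribution:
    def test_discard_rule_and_counts(self):
        dmap = DiameterMap.from_diameters(np.array([1.0, 1.0, 0.05]))
        stats, counts = roi_diameter_distribution(dmap)
        assert stats.n == 2 and stats.mean == pytest.approx(1.0)
        assert counts["n_discarded"] == 1 and counts["n_zero"] == 0
        assert counts["n_valid"] + counts["n_zero"] + counts["n_discarded"] \
            + counts["n_invalid"] == counts["n_roi"]

    def test_single_voxel_roi(self):
        dmap = DiameterMap.from_diameters(np.array([0.8]))
        stats, _ = roi_diameter_distribution(dmap)
        assert stats.mode == stats.mean == stats.p90 == pytest.approx(0.8)
        assert stats.sd == 0.0

    def test_all_discarded_raises(self):
        dmap = DiameterMap.from_diameters(np.array([0.0, 0.0, 0.02]))
        with pytest.raises(EmptyDistributionError):
            roi_diameter_distribution(dmap)
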