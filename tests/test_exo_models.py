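"""Depletion, Hill, activation-tau, IV and charge measurements."""

import numpy as np
import pandas as pd
import pytest

from azphys.errors import FitError, InvalidParameterError
from azphys.exo_models import (build_iv, fit_activation_tau, fit_boltzmann_iv,
                               fit_depletion, fit_hill, peak_current,
                               total_ca_charge)
from azphys.params import CaChannelParams, ReleaseParams
from azphys.synth_ephys import (CurrentTrace, ca_current_peak_analytic,
                                simulate_ca_current,
                                simulate_depletion_dataset)


def trace_of(i, fs=50.0, t0=0.0):
    return CurrentTrace(np.asarray(i, float), fs, t0)


class TestPeakCurrent:
    def test_constructed_minimum(self):
        i = np.zeros(1000)
        i[400] = -44.0
        assert peak_current(trace_of(i), (5, 15)) == 44.0
        assert peak_current(trace_of(i), (5, 15), signed=True) == -44.0

    def test_flat_trace(self):
        assert peak_current(trace_of(np.zeros(500)), (2, 8)) == 0.0

    def test_matches_closed_form(self):
        chan = CaChannelParams()
        trace = simulate_ca_current(chan, 10.0, 20.0)
        got = peak_current(trace, (0.0, 20.0))
        want = abs(ca_current_peak_analytic(chan, 10.0, 20.0))
        assert got == pytest.approx(want, rel=5e-3)

    def test_baseline_offset_invariance(self):
        chan = CaChannelParams()
        trace = simulate_ca_current(chan, 10.0, 20.0)
        shifted = trace_of(trace.i_pA + 250.0, trace.fs_khz, trace.t0_ms)
        assert peak_current(shifted, (0.0, 20.0)) == pytest.approx(
            peak_current(trace, (0.0, 20.0)), rel=1e-9)


class TestTotalCharge:
    def test_rectangle(self):
        """Constant -44 pA for 100 ms integrates to 4.4 pC."""
        i = np.concatenate([np.zeros(100), np.full(5100, -44.0)])
        tr = trace_of(i, fs=50.0, t0=-2.0)
        assert total_ca_charge(tr, (0.0, 100.0)) == pytest.approx(4.4,
                                                                  rel=1e-3)

    def test_zero_trace(self):
        assert total_ca_charge(trace_of(np.zeros(1000)), (0, 10)) == 0.0

    def test_exponential_activation_integral(self):
        """Charge of I(t) = I_ss(1-exp(-t/tau)) matches the closed form
        I_ss (T - tau (1 - exp(-T/tau)))."""
        chan = CaChannelParams(tau_act_ms=1.4)
        T = 50.0
        trace = simulate_ca_current(chan, 10.0, T, fs_khz=100)
        i_ss = abs(ca_current_peak_analytic(chan, 10.0))
        tau = chan.tau_act_ms
        q_true = i_ss * (T - tau * (1 - np.exp(-T / tau))) / 1000.0
        assert total_ca_charge(trace, (0.0, T)) == pytest.approx(q_true,
                                                                 rel=1e-3)


class TestDepletionFit:
    def test_exact_roundtrip(self):
        rel = ReleaseParams(rrp_size_fF=52, tau_release_ms=59, hill_K_pA=0)
        df = simulate_depletion_dataset(rel, CaChannelParams(),
                                        [5, 10, 20, 50, 100])
        fit = fit_depletion(df)
        assert fit.c_inf_fF == pytest.approx(52.0, rel=1e-6)
        assert fit.tau_ms == pytest.approx(59.0, rel=1e-6)
        assert fit.residual_rms_fF < 1e-8

    def test_two_durations_rejected(self):
        df = pd.DataFrame({"duration_ms": [5, 100], "dcm_fF": [10, 50]})
        with pytest.raises(InvalidParameterError):
            fit_depletion(df)

    def test_monte_carlo_tau_bias(self):
        """A replicate is a 9-terminal experiment (5 fF noise per
        measurement, pooled fit, the published design): mean recovered tau
        stays within 10% of truth.  A single noisy 5-point dataset has a
        median-centred but heavily right-skewed tau-hat -- the documented
        non-plateau caveat."""
        rel = ReleaseParams(rrp_size_fF=52, tau_release_ms=59, hill_K_pA=0)
        chan = CaChannelParams()
        taus = []
        for s in range(60):
            cells = [simulate_depletion_dataset(
                rel, chan, [5, 10, 20, 50, 100], seed=1000 * s + c,
                noise_sd_fF=5.0) for c in range(9)]
            taus.append(fit_depletion(pd.concat(cells)).tau_ms)
        assert abs(np.mean(taus) - 59.0) / 59.0 < 0.10

        singles = [fit_depletion(simulate_depletion_dataset(
            rel, chan, [5, 10, 20, 50, 100], seed=s, noise_sd_fF=5.0)
            ).tau_ms for s in range(60)]
        assert abs(np.median(singles) - 59.0) / 59.0 < 0.10
        assert np.mean(singles) > 59.0 * 1.10   # skew: mean overshoots

    def test_covariance_shape(self):
        rel = ReleaseParams(rrp_size_fF=52, tau_release_ms=59, hill_K_pA=0)
        df = simulate_depletion_dataset(rel, CaChannelParams(),
                                        [5, 10, 20, 50, 100],
                                        seed=0, noise_sd_fF=2.0)
        fit = fit_depletion(df)
        assert np.asarray(fit.cov).shape == (2, 2)
        assert np.all(np.diag(fit.cov) >= 0)


class TestActivationTau:
    @pytest.mark.parametrize("tau", [1.4, 1.3])
    def test_roundtrip(self, tau):
        chan = CaChannelParams(tau_act_ms=tau)
        trace = simulate_ca_current(chan, 10.0, 10.0)
        assert fit_activation_tau(trace, (0.0, 10.0)) == pytest.approx(
            tau, rel=0.01)

    def test_step_current_below_resolution(self):
        i = np.concatenate([np.zeros(100), np.full(500, -40.0)])
        with pytest.raises(FitError):
            fit_activation_tau(trace_of(i, t0=-2.0), (0.0, 10.0))


class TestIV:
    def make_traces(self, chan):
        return {v: simulate_ca_current(chan, v, 5.0)
                for v in np.arange(-80, 71, 10.0)}

    def test_extremum_and_reversal(self):
        chan = CaChannelParams()
        iv = build_iv(self.make_traces(chan), (0.0, 5.0))
        vmin = iv.loc[iv["i_peak_pA"].idxmin(), "v_mV"]
        assert vmin == 10.0
        # at a level equal to E_rev the current vanishes
        trace = simulate_ca_current(chan, chan.e_rev_mV, 5.0)
        iv2 = build_iv({chan.e_rev_mV: trace}, (0.0, 5.0))
        assert iv2["i_peak_pA"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_missing_level_left_absent(self):
        chan = CaChannelParams()
        traces = self.make_traces(chan)
        del traces[0.0]
        iv = build_iv(traces, (0.0, 5.0))
        assert 0.0 not in iv["v_mV"].values
        assert len(iv) == 15

    def test_boltzmann_fit_recovers_gating(self):
        chan = CaChannelParams()
        # evaluate at steady state to avoid activation-kinetics bias
        iv = pd.DataFrame({
            "v_mV": np.arange(-80, 71, 10.0),
            "i_peak_pA": [ca_current_peak_analytic(chan, v)
                          for v in np.arange(-80, 71, 10.0)]})
        fit = fit_boltzmann_iv(iv)
        assert fit["v_half_mV"] == pytest.approx(chan.v_half_mV, abs=0.1)
        assert fit["k_slope_mV"] == pytest.approx(chan.k_slope_mV, rel=0.02)
        assert fit["e_rev_mV"] == pytest.approx(chan.e_rev_mV, rel=0.02)


class TestHillFit:
    def test_exact_roundtrip(self):
        i = np.array([10, 20, 30, 44, 54.0])
        y = 52 * i**3 / (i**3 + 30.0**3)
        fit = fit_hill(i, y, n=3)
        assert fit.c_max_fF == pytest.approx(52.0, rel=1e-6)
        assert fit.k_pA == pytest.approx(30.0, rel=1e-6)

    def test_half_saturation_identity(self):
        fit = fit_hill([10, 20, 30, 44, 54.0],
                       52 * np.array([10, 20, 30, 44, 54.0])**3
                       / (np.array([10, 20, 30, 44, 54.0])**3 + 30.0**3))
        assert fit.predict(fit.k_pA) == pytest.approx(fit.c_max_fF / 2)

    def test_scale_equivariance(self):
        """Scaling all currents and K by the same factor leaves the
        residuals unchanged."""
        i = np.array([10, 20, 30, 44, 54.0])
        y = 52 * i**3 / (i**3 + 30.0**3) + np.array([1, -1, 2, 0, -2.0])
        f1 = fit_hill(i, y, n=3)
        f2 = fit_hill(i * 7.0, y, n=3)
        assert f2.k_pA == pytest.approx(7.0 * f1.k_pA, rel=1e-4)
        assert f2.residual_rms_fF == pytest.approx(f1.residual_rms_fF,
                                                   rel=1e-4)

    def test_n3_beats_n1_on_cooperative_data(self):
        rng = np.random.default_rng(0)
        i = np.array([10, 15, 22, 30, 44, 54.0])
        y = 52 * i**3 / (i**3 + 30.0**3) + rng.normal(0, 0.5, i.size)
        assert fit_hill(i, y, n=3).residual_rms_fF < fit_hill(
            i, y, n=1).residual_rms_fF

    def test_fixed_cmax_mode(self):
        i = np.array([10, 20, 30, 44, 54.0])
        y = 52 * i**3 / (i**3 + 30.0**3)
        fit = fit_hill(i, y, n=3, c_max_fixed=52.0)
        assert fit.c_max_fixed
        assert fit.k_pA == pytest.approx(30.0, rel=1e-6)

    def test_degenerate_currents_rejected(self):
        with pytest.raises(FitError):
            fit_hill([30, 30, 30.0], [10, 11, 12.0], n=3)
        with pytest.raises(InvalidParameterError):
            fit_hill([10, -5, 30.0], [1, 2, 3.0], n=3)
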