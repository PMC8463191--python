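"""Waveform synthesis, gating schedules and the RMS metric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thalcor.stimulation import (StimulusProtocol, cbbp_waveform, crs_gates,
                                 dbs_waveform, rms_current, stimulus_currents)


def protocol(kind, **kw):
    return StimulusProtocol(kind=kind, **kw)


class TestDBS:
    def test_on_off_values_at_clinical_settings(self):
        # alpha = 2 mA, f = 130 Hz, delta = 4 ms: pulse fills the first
        # 4 ms of each ~7.69 ms period
        p = protocol("dbs", amplitude=2.0, frequency=130.0, pulse_width=0.004)
        assert dbs_waveform(0.001, p) == pytest.approx(2.0)
        assert dbs_waveform(0.006, p) == pytest.approx(0.0)

    def test_zero_amplitude_is_identically_zero(self):
        p = protocol("dbs", amplitude=0.0)
        t = np.linspace(0, 1, 5000)
        assert np.all(dbs_waveform(t, p) == 0.0)

    def test_exact_periodicity_on_sample_grid(self):
        p = protocol("dbs", amplitude=2.0)
        t = np.arange(0, 10 * p.period, 0.25e-3)
        np.testing.assert_array_equal(dbs_waveform(t, p),
                                      dbs_waveform(t + 3 * p.period, p))

    def test_rms_matches_duty_cycle_closed_form(self):
        """RMS over an integer number of periods is alpha*sqrt(delta/rho);
        the oracle is direct quadrature of u^2 on a fine grid."""
        p = protocol("dbs", amplitude=2.0, frequency=130.0, pulse_width=0.004)
        n_per = 10
        t = np.arange(0, n_per * p.period, p.period / 20000)
        u = dbs_waveform(t, p)
        quadrature = np.sqrt(np.mean(u ** 2))
        closed = 2.0 * np.sqrt(0.004 * 130.0)
        assert closed == pytest.approx(1.44222, abs=1e-5)
        assert quadrature == pytest.approx(closed, rel=1e-3)
        assert rms_current(u) == pytest.approx(quadrature, rel=1e-12)

    def test_pulse_wider_than_period_rejected(self):
        with pytest.raises(ValueError):
            protocol("dbs", frequency=130.0, pulse_width=0.01)


class TestCBBP:
    def test_literal_amplitudes(self):
        # printed convention: anodic value delta, cathodic -delta/(T-delta)
        p = protocol("cbbp", frequency=130.0, pulse_width=0.004)
        T = p.period
        assert cbbp_waveform(0.002, p) == pytest.approx(0.004)
        assert cbbp_waveform(0.005, p) == pytest.approx(-0.004 / (T - 0.004))

    def test_literal_net_charge(self):
        # delta*delta + (T-delta)*(-delta/(T-delta)) = delta^2 - delta
        p = protocol("cbbp", frequency=130.0, pulse_width=0.004)
        T = p.period
        t = np.arange(0, T, T / 2_000_000)
        charge = np.sum(cbbp_waveform(t, p)) * (T / 2_000_000)
        assert charge == pytest.approx(0.004 ** 2 - 0.004, abs=1e-8)

    def test_charge_balanced_variant_zero_net_charge(self):
        p = protocol("cbbp", amplitude=2.0, frequency=130.0,
                     pulse_width=0.004, cbbp_literal=False)
        T = p.period
        t = np.arange(0, T, T / 2_000_000)
        charge = np.sum(cbbp_waveform(t, p)) * (T / 2_000_000)
        assert abs(charge) < 1e-12 * 2.0 * T * 1e6  # quadrature tolerance

    def test_charge_balanced_cathodic_amplitude(self):
        # -alpha*delta/(T-delta) with alpha=2: ~ -2.16667
        p = protocol("cbbp", amplitude=2.0, frequency=130.0,
                     pulse_width=0.004, cbbp_literal=False)
        assert cbbp_waveform(0.006, p) == pytest.approx(-2.16667, abs=2e-5)
        # anodic phase membership at t = PT + delta/2
        assert cbbp_waveform(5 * p.period + 0.002, p) == pytest.approx(2.0)

    def test_pulse_wider_than_biphasic_period_rejected(self):
        with pytest.raises(ValueError):
            protocol("cbbp", frequency=130.0, pulse_width=0.009)


class TestCRSGates:
    def test_one_zero_alternates_starting_with_trn1(self):
        p = protocol("crs", crs_m=1, crs_n=0, crs_cycle_length=0.1)
        mid = lambda c: 0.1 * c + 0.05
        for cycle, expected in [(0, (1, 0)), (1, (0, 1)), (2, (1, 0)),
                                (3, (0, 1))]:
            b1, b2 = crs_gates(mid(cycle), p)
            assert (b1, b2) == expected

    def test_three_two_pattern(self):
        """Three alternating ON cycles (TRN1, TRN2, TRN1) then two OFF;
        alternation continues across super-periods."""
        p = protocol("crs", crs_m=3, crs_n=2, crs_cycle_length=0.1)
        mid = lambda c: 0.1 * c + 0.05
        expected = [(1, 0), (0, 1), (1, 0), (0, 0), (0, 0),
                    (0, 1), (1, 0), (0, 1), (0, 0), (0, 0)]
        got = [tuple(map(float, crs_gates(mid(c), p))) for c in range(10)]
        assert got == [tuple(map(float, e)) for e in expected]

    @settings(max_examples=50, derandomize=True)
    @given(t=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
           m=st.integers(min_value=1, max_value=5),
           n=st.integers(min_value=0, max_value=5))
    def test_mutual_exclusion(self, t, m, n):
        p = protocol("crs", crs_m=m, crs_n=n, crs_cycle_length=0.25)
        b1, b2 = crs_gates(t, p)
        assert float(b1) * float(b2) == 0.0
        assert float(b1) in (0.0, 1.0) and float(b2) in (0.0, 1.0)

    def test_gates_depend_only_on_cycle_index(self):
        p = protocol("crs", crs_m=3, crs_n=2, crs_cycle_length=1 / 3)
        for c in range(12):
            times = 1 / 3 * c + np.array([1e-6, 0.1, 0.2, 1 / 3 - 1e-6])
            b1, b2 = crs_gates(times, p)
            assert len(set(b1)) == 1 and len(set(b2)) == 1

    def test_zero_on_cycles_rejected(self):
        with pytest.raises(ValueError):
            protocol("crs", crs_m=0)


class TestStimulusCurrents:
    def test_none_is_zero(self):
        u1, u2 = stimulus_currents(np.linspace(0, 1, 100), StimulusProtocol())
        assert not u1.any() and not u2.any()

    def test_dbs_drives_both_targets_identically(self):
        t = np.linspace(0, 0.1, 1000)
        u1, u2 = stimulus_currents(t, protocol("dbs"))
        np.testing.assert_array_equal(u1, u2)

    def test_crs_splits_the_pulse_train(self):
        t = np.linspace(0, 2.0, 4001)
        p = protocol("crs", crs_m=1, crs_n=0, crs_cycle_length=1 / 3)
        u1, u2 = stimulus_currents(t, p)
        full = dbs_waveform(t, p.replace(kind="dbs"))
        np.testing.assert_array_equal(u1 + u2, full)
        assert not np.any((u1 > 0) & (u2 > 0))


class TestRMS:
    def test_constant_signal(self):
        assert rms_current(np.full(17, -3.5)) == pytest.approx(3.5)

    def test_zero_signal(self):
        assert rms_current(np.zeros(5)) == 0.0

    def test_square_wave_duty_closed_form(self):
        # amplitude alpha, duty d -> alpha*sqrt(d); oracle is the direct sum
        alpha, d, n = 1.7, 0.3, 10000
        u = np.zeros(n)
        u[: int(d * n)] = alpha
        direct = np.sqrt(np.sum(u ** 2) / n)
        assert rms_current(u) == pytest.approx(direct, rel=1e-14)
        assert rms_current(u) == pytest.approx(alpha * np.sqrt(d), rel=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_permutation_invariant_and_amplitude_linear(self, scale):
        rng = np.random.default_rng(5)
        u = rng.normal(size=256)
        shuffled = rng.permutation(u)
        assert rms_current(shuffled) == pytest.approx(rms_current(u), rel=1e-12)
        assert rms_current(scale * u) == pytest.approx(
            scale * rms_current(u), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rms_current([])
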