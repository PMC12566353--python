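"""Amplifier stage models: transfer functions, slew/settling error, noise."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, signal as sps

from spikechain import (
    AmplifierParams,
    StageRole,
    compute_derived,
    default_lna,
    default_pga,
    gm_for_gbw,
    lna_closed_loop_tf,
    lna_open_loop_tf,
    pga_closed_loop_tf,
    process_amplifier,
    slew_error,
    sr_from_ids,
    white_noise,
)
from spikechain.metrics import tone_metrics, welch_psd
from spikechain.synth import generate_test_tone


def tf_mag(tf, f_hz):
    w, h = sps.freqresp(tf, w=2 * math.pi * np.atleast_1d(f_hz))
    return np.abs(h)


class TestParams:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            AmplifierParams(Cin=20e-12, Cf=0.0, Cl=1e-12, Gm=60e-6)
        with pytest.raises(ValueError):
            AmplifierParams(Cin=-1e-12, Cf=200e-15, Cl=1e-12, Gm=60e-6)

    def test_gbw_gm_consistency_enforced(self):
        # GBW = Gm/(2 pi Cl) must hold to 1% when both are given
        with pytest.raises(ValueError):
            AmplifierParams(Cin=20e-12, Cf=200e-15, Cl=1e-12, Gm=62.8e-6,
                            GBW=20e6)
        p = AmplifierParams(Cin=20e-12, Cf=200e-15, Cl=1e-12, GBW=10e6)
        assert p.Gm == pytest.approx(62.8e-6, rel=1e-2)

    def test_ids_ratio_consistency(self):
        p = default_lna()
        ids = p.Gm * 1e-5 / (4 * math.pi)  # SR/GBW = 1e-5 V
        ok = replace(p, SR=1e-5 * p.GBW, Ids=ids)
        assert ok.Ids == ids
        with pytest.raises(ValueError):
            replace(p, SR=1e-5 * p.GBW, Ids=ids * 3)

    def test_scaled_speed_keeps_ratio(self):
        p = replace(default_lna(), SR=120.0)
        q = p.scaled_speed(2.5)
        assert q.SR / q.GBW == pytest.approx(p.SR / p.GBW)
        assert q.GBW == pytest.approx(2.5 * p.GBW)


class TestDerived:
    def test_worked_sizing_example(self):
        # Cin=20 pF, Cl=1 pF, Cf=200 fF, Gm=62.8 uA/V -> tau = 10 us,
        # which equals midband_gain / GBW at GBW = 10 MHz
        p = AmplifierParams(Cin=20e-12, Cf=200e-15, Cl=1e-12, Gm=62.8e-6)
        d = compute_derived(p)
        assert d.tau == pytest.approx(10e-6, rel=1e-3)
        assert d.tau == pytest.approx(d.midband_gain / p.GBW, rel=1e-6)
        assert d.midband_gain == pytest.approx(100.0)

    def test_beta_midband_arithmetic(self):
        p = AmplifierParams(Cin=20e-12, Cf=200e-15, Cl=1e-12, Cp=0.0, Gm=62.8e-6)
        d = compute_derived(p)
        assert d.beta == pytest.approx(200e-15 / 20.2e-12, rel=1e-9)
        assert d.beta == pytest.approx(9.90e-3, rel=1e-3)
        assert d.CL_eff == pytest.approx(p.Cl + (1 - d.beta) * p.Cf)
        assert d.CL_eff >= p.Cl

    def test_gm_for_gbw_and_sr_helpers(self):
        assert gm_for_gbw(10e6, 1e-12) == pytest.approx(62.8e-6, rel=1e-3)
        assert sr_from_ids(1e-6, 1e-12) == pytest.approx(2e6)


class TestTransferFunctions:
    def test_lna_midband_gain_40db(self):
        tf = lna_closed_loop_tf(default_lna(noise=False))
        mag = tf_mag(tf, 1000.0)[0]
        assert 20 * np.log10(mag) == pytest.approx(40.0, abs=0.2)

    def test_lna_dc_blocked(self):
        tf = lna_closed_loop_tf(default_lna(noise=False))
        assert np.polyval(tf.num, 0.0) == 0.0

    def test_lna_highpass_corner(self):
        # -3 dB point of the pseudo-resistor zero: 1/(2 pi Rf Cf) ~ 79.6 Hz
        p = default_lna(noise=False)
        tf = lna_closed_loop_tf(p)
        mid = tf_mag(tf, 2000.0)[0]
        f3 = optimize.brentq(lambda f: tf_mag(tf, f)[0] - mid / math.sqrt(2), 1.0, 2000.0)
        assert f3 == pytest.approx(1 / (2 * math.pi * p.Rf * p.Cf), rel=0.02)
        assert f3 == pytest.approx(79.6, rel=0.02)

    def test_pga_dc_gain_and_corner(self):
        p = default_pga(noise=False)
        tf = pga_closed_loop_tf(p)
        assert tf_mag(tf, 1e-3)[0] == pytest.approx(p.Cin / p.Cf, rel=1e-6)
        d = compute_derived(p)
        f_expect = p.Gm * d.beta / (2 * math.pi * d.CL_eff)
        mid = tf_mag(tf, 1e-3)[0]
        f3 = optimize.brentq(
            lambda f: tf_mag(tf, f)[0] - mid / math.sqrt(2), 1.0, 1e9
        )
        assert f3 == pytest.approx(f_expect, rel=0.02)

    def test_open_loop_dc_and_pole(self):
        p = default_lna(noise=False)
        d = compute_derived(p)
        tf = lna_open_loop_tf(p)
        assert tf_mag(tf, 1e-6)[0] == pytest.approx(p.Gm * p.Ro * d.beta, rel=1e-6)
        pole = 1 / (2 * math.pi * p.Ro * d.CL_eff)
        assert tf_mag(tf, pole)[0] == pytest.approx(
            tf_mag(tf, 1e-6)[0] / math.sqrt(2), rel=1e-3
        )

    def test_closed_loop_from_open_loop(self):
        # H_o/(1 + H_o/F) with F the ideal feedback matches the closed-loop
        # form at mid-band when the loop gain there is large; a fast OTA
        # keeps the in-band loop gain above 100x the closed-loop target
        p = AmplifierParams(Cin=20e-12, Cf=200e-15, Cl=1e-12, Gm=62.8e-3,
                            Ro=1e9, role=StageRole.LNA)
        d = compute_derived(p)
        assert p.Gm * p.Ro * d.beta > 100
        f = np.geomspace(300, 3000, 7)
        w = 2 * math.pi * f
        s = 1j * w
        ho = np.squeeze(sps.freqresp(lna_open_loop_tf(p), w=w)[1])
        feedback = -p.Cin / (p.Cf + 1.0 / (s * p.Rf))  # closed-loop target 1/F
        hc_from_open = ho / (1 + ho / feedback)
        hc = np.squeeze(sps.freqresp(lna_closed_loop_tf(p), w=w)[1])
        assert np.allclose(np.abs(hc_from_open), np.abs(hc), rtol=0.01)


class TestSlewError:
    def test_unlimited_sr_is_pure_settling(self):
        p = default_lna(noise=False)
        tau = compute_derived(p).tau
        r = slew_error(100e-6, p, Ts=1 / 24000.0)
        assert r.case_id == 3
        assert r.error == pytest.approx(100e-6 * math.exp(-(1 / 48000.0) / tau))

    def test_zero_input(self):
        r = slew_error(0.0, default_lna(noise=False), Ts=1e-4)
        assert r.case_id == 3 and r.slope == 0.0 and r.error == 0.0

    def test_case1_rate_deficit(self):
        # deep slewing: error equals the distance not covered at rate SR
        p = replace(default_lna(noise=False), SR=10.0)
        ts = 1 / 24000.0
        r = slew_error(5e-3, p, Ts=ts)
        assert r.case_id == 1
        assert r.t_sl >= ts / 2
        assert r.error == pytest.approx(5e-3 - 10.0 * ts / 2)

    @given(
        vin=st.floats(1e-7, 1e-1),
        sr=st.floats(1e-2, 1e5),
        ts_us=st.floats(1.0, 100.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_case_partition_and_positivity(self, vin, sr, ts_us):
        p = replace(default_lna(noise=False), SR=sr)
        r = slew_error(vin, p, Ts=ts_us * 1e-6)
        assert r.case_id in (1, 2, 3)
        assert r.error >= 0.0
        assert r.t_sl >= 0.0 and r.t_lin >= 0.0
        tau = compute_derived(p).tau
        if r.case_id == 3:
            assert r.slope <= sr
        else:
            assert r.slope > sr

    def test_continuity_across_case_boundary(self):
        # at t_sl = Ts/2 the case-1 and case-2 formulas agree
        p = replace(default_lna(noise=False), SR=50.0)
        tau = compute_derived(p).tau
        ts = 1 / 24000.0
        v_star = 50.0 * (tau + ts / 2)  # step whose required t_sl is Ts/2
        lo = slew_error(v_star * (1 - 1e-9), p, Ts=ts)
        hi = slew_error(v_star * (1 + 1e-9), p, Ts=ts)
        assert lo.case_id != hi.case_id
        assert lo.error == pytest.approx(hi.error, rel=1e-6)


class TestWhiteNoise:
    def test_zero_floor_and_determinism(self):
        assert not white_noise(100, 0.0, 24000.0, 3).any()
        a = white_noise(1000, 1e-12, 24000.0, 7)
        b = white_noise(1000, 1e-12, 24000.0, 7)
        assert np.array_equal(a, b)

    def test_psd_floor_recovered(self):
        fs, floor = 24000.0, 4e-12
        x = white_noise(2**20, floor, fs, 11)
        f, pxx = welch_psd(x, fs, 4096)
        measured = np.median(pxx)
        assert measured == pytest.approx(floor, rel=0.05)


class TestProcessAmplifier:
    def test_linear_limit_equals_direct_filter(self):
        p = default_lna(noise=False)
        fs = 24000.0
        x = generate_test_tone(1110.0, 100e-6, fs, 0.5)
        y = process_amplifier(x, fs, p, seed=0)
        tf = lna_closed_loop_tf(p)
        b, a = sps.bilinear(tf.num, tf.den, fs)
        y_ref = sps.lfilter(b, a, x)
        fs_scale = np.max(np.abs(y_ref))
        assert np.max(np.abs(y - y_ref)) < 1e-9 * fs_scale

    def test_midband_gain_law(self):
        fs = 24000.0
        for params, amp in ((default_lna(noise=False), 100e-6),
                            (default_pga(noise=False), 1e-3)):
            x = generate_test_tone(1110.0, amp, fs, 0.5)
            y = process_amplifier(x, fs, params, seed=0)
            gain = tone_metrics(y, fs, 1110.0).fundamental_amp / amp
            assert gain == pytest.approx(params.Cin / params.Cf, rel=0.02)

    def test_clean_tone_low_distortion(self):
        # linear mode: residual THD is discretization-limited, far below -50 dB
        fs = 24000.0
        x = generate_test_tone(1110.0, 100e-6, fs, 1.0)
        y = process_amplifier(x, fs, default_lna(noise=False), seed=0)
        assert tone_metrics(y, fs, 1110.0).thd_db <= -50.0

    def test_noise_floor_referred_to_output(self):
        p = replace(default_lna(), noise_floor=1e-14)
        fs = 24000.0
        y = process_amplifier(np.zeros(2**19), fs, p, seed=5)
        f, pxx = welch_psd(y, fs, 4096)
        gain = p.Cin / p.Cf
        # mid-band floor (inside the amplifier passband)
        band = (f > 500) & (f < 5000)
        assert np.median(pxx[band]) == pytest.approx(
            1e-14 * gain**2, rel=0.10
        )

    def test_thd_monotone_as_sr_decreases(self):
        fs = 24000.0
        x = generate_test_tone(1110.0, 100e-6, fs, 1.0)
        thds = []
        for sr in (400.0, 200.0, 100.0, 50.0):
            p = replace(default_lna(noise=False), SR=sr)
            y = process_amplifier(x, fs, p, seed=0)
            thds.append(tone_metrics(y, fs, 1110.0).thd_db)
        assert all(t2 >= t1 - 1e-9 for t1, t2 in zip(thds, thds[1:]))
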