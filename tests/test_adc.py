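"""Flash ADC behavioral model: ladder, quantization, INL/DNL, noise laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikechain import (
    AdcParams,
    adc_chain,
    build_reference_ladder,
    codes_to_voltage,
    ideal_snr_db,
    inl_dnl,
    quantize,
)
from spikechain.metrics import tone_metrics
from spikechain.synth import generate_test_tone


def ideal_2bit():
    return build_reference_ladder(AdcParams(n_bits=2, v_min=-1.0, v_max=1.0))


class TestLadder:
    def test_ideal_2bit_thresholds(self):
        lad = ideal_2bit()
        assert np.allclose(lad.thresholds, [-0.5, 0.0, 0.5])
        assert lad.lsb == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_count_and_strict_monotonicity(self, seed):
        lad = build_reference_ladder(
            AdcParams(n_bits=10, perturb_sigma=2.0, seed=seed)
        )
        assert len(lad.thresholds) == 2**10 - 1
        assert np.all(np.diff(lad.thresholds) > 0)

    def test_perturbation_scale(self):
        p = AdcParams(n_bits=12, perturb_sigma=0.3, seed=4)
        lad = build_reference_ladder(p)
        ideal = p.v_min + p.lsb * np.arange(1, 2**12)
        sd = np.std((lad.thresholds - ideal) / p.lsb)
        assert sd == pytest.approx(0.3, rel=0.10)


class TestQuantize:
    def test_counting_and_saturation(self):
        lad = ideal_2bit()
        assert quantize(np.array([0.75]), lad)[0] == 3
        assert quantize(np.array([-2.0]), lad)[0] == 0
        assert quantize(np.array([2.0]), lad)[0] == 3

    def test_monotone_on_grid(self):
        lad = build_reference_ladder(AdcParams(n_bits=8, perturb_sigma=1.5, seed=3))
        x = np.linspace(-0.4, 0.4, 1000)
        codes = quantize(x, lad)
        # brute-force oracle: counting thresholds below each sample
        oracle = np.array([(lad.thresholds < v).sum() for v in x])
        assert np.array_equal(codes, oracle)
        assert np.all(np.diff(codes) >= 0)

    def test_roundtrip_bound_and_code0(self):
        lad = ideal_2bit()
        v = np.linspace(-0.999, 0.999, 501)
        back = codes_to_voltage(quantize(v, lad), lad)
        assert np.max(np.abs(back - v)) <= lad.lsb / 2 + 1e-12
        assert codes_to_voltage(np.array([0]), lad)[0] == pytest.approx(
            lad.v_min + lad.lsb / 2
        )


class TestInlDnl:
    def test_ideal_ladder_zero(self):
        inl, dnl = inl_dnl(ideal_2bit())
        assert not inl.any() and not dnl.any()

    @pytest.mark.parametrize("sigma,seed", [(0.3, 0), (1.0, 1), (5.0, 2)])
    def test_telescoping_identity(self, sigma, seed):
        lad = build_reference_ladder(
            AdcParams(n_bits=10, perturb_sigma=sigma, seed=seed)
        )
        inl, dnl = inl_dnl(lad)
        assert len(inl) == 2**10 - 1 and len(dnl) == 2**10 - 2
        assert np.allclose(np.diff(inl), dnl, atol=1e-10)

    def test_halflsb_sigma_usually_exceeds_one_lsb_dnl(self):
        hits = 0
        for seed in range(20):
            lad = build_reference_ladder(
                AdcParams(n_bits=12, perturb_sigma=0.5, seed=seed)
            )
            _, dnl = inl_dnl(lad)
            hits += np.max(np.abs(dnl)) > 1.0
        assert hits >= 15  # typical behavior on a 12-bit ladder


class TestChain:
    @pytest.mark.parametrize("n_bits", [8, 10, 12])
    def test_quantization_noise_law(self, n_bits):
        p = AdcParams(n_bits=n_bits, noise_floor=0.0)
        amp = 0.99 * (p.v_max - p.v_min) / 2
        x = generate_test_tone(1110.0, amp, 24000.0, 1.0)
        y = adc_chain(x, 24000.0, p)
        m = tone_metrics(y, 24000.0, 1110.0)
        assert m.snr_db == pytest.approx(ideal_snr_db(n_bits), abs=0.3)

    def test_zero_input_constant_midcode(self):
        p = AdcParams(n_bits=12, noise_floor=0.0)
        y = adc_chain(np.zeros(256), 24000.0, p)
        assert np.ptp(y) == 0.0
        assert abs(y[0]) <= p.lsb

    def test_enob_nonincreasing_in_perturbation(self):
        p0 = AdcParams(n_bits=12, noise_floor=0.0)
        amp = 0.99 * (p0.v_max - p0.v_min) / 2
        x = generate_test_tone(1110.0, amp, 24000.0, 1.0)
        med = []
        for sigma in (0.0, 8.0, 80.0):
            enobs = []
            for seed in range(10):
                p = AdcParams(n_bits=12, perturb_sigma=sigma,
                              noise_floor=0.0, seed=seed)
                enobs.append(tone_metrics(adc_chain(x, 24000.0, p),
                                          24000.0, 1110.0).enob_bits)
            med.append(np.median(enobs))
        assert med[0] > med[1] > med[2]

    def test_noise_floor_rises_about_6db_per_bit(self):
        # resolution sweep: each bit removed lifts the quantization floor ~6 dB
        snrs = []
        for n_bits in (12, 10, 8):
            p = AdcParams(n_bits=n_bits, noise_floor=0.0)
            amp = 0.99 * (p.v_max - p.v_min) / 2
            x = generate_test_tone(1110.0, amp, 24000.0, 1.0)
            snrs.append(tone_metrics(adc_chain(x, 24000.0, p), 24000.0, 1110.0).snr_db)
        per_bit = (snrs[0] - snrs[2]) / 4
        assert per_bit == pytest.approx(6.02, abs=0.5)

    def test_determinism_under_seed(self):
        p = AdcParams(n_bits=10, perturb_sigma=3.0, noise_floor=1e-12, seed=9)
        x = generate_test_tone(1110.0, 0.2, 24000.0, 0.2)
        assert np.array_equal(adc_chain(x, 24000.0, p), adc_chain(x, 24000.0, p))


@given(st.floats(-1.5, 1.5))
@settings(max_examples=100, deadline=None, derandomize=True)
def test_quantize_reconstruct_never_escapes_range(v):
    lad = ideal_2bit()
    back = codes_to_voltage(quantize(np.array([v]), lad), lad)[0]
    assert lad.v_min < back < lad.v_max
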