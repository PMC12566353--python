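"""Behavioral n-bit flash ADC with a Gaussian-perturbed reference ladder.

The converter compares each sample against 2^n - 1 ladder thresholds
(thermometer code -> binary).  Static resistor mismatch is emulated by adding
one Gaussian perturbation per threshold (drawn once per ladder, then re-sorted
to keep the transfer monotone, as a bubble-corrected flash encoder would
behave).  Reconstruction is mid-tread with the *ideal* LSB: the decoder does
not know the mismatch, which is what turns INL/DNL into harmonic distortion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .frontend import white_noise

__all__ = [
    "AdcParams",
    "ReferenceLadder",
    "build_reference_ladder",
    "quantize",
    "codes_to_voltage",
    "inl_dnl",
    "adc_chain",
    "ideal_snr_db",
]


@dataclass
class AdcParams:
    """Flash ADC configuration.

    perturb_sigma is the threshold-perturbation standard deviation in units
    of one LSB (0 = ideal ladder); noise_floor is the one-sided PSD of the
    input thermal-noise source in V^2/Hz.
    """

    n_bits: int = 12
    v_min: float = -0.35
    v_max: float = 0.35
    perturb_sigma: float = 0.0
    noise_floor: float = 1e-15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bits < 2:
            raise ValueError("n_bits must be at least 2")
        if self.v_max <= self.v_min:
            raise ValueError("v_max must exceed v_min")
        if self.perturb_sigma < 0:
            raise ValueError("perturb_sigma must be non-negative")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")

    @property
    def lsb(self) -> float:
        return (self.v_max - self.v_min) / 2**self.n_bits


@dataclass(frozen=True)
class ReferenceLadder:
    thresholds: np.ndarray = field(repr=False)
    lsb: float
    v_min: float
    v_max: float
    n_bits: int

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if len(t) != 2**self.n_bits - 1:
            raise ValueError("ladder must have 2^n - 1 thresholds")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")


def build_reference_ladder(params: AdcParams) -> ReferenceLadder:
    """Mid-rise thresholds t_i = v_min + i*lsb (i = 1..2^n-1), each shifted by
    N(0, (perturb_sigma*lsb)^2) and re-sorted for monotonicity."""
    n_levels = 2**params.n_bits
    lsb = params.lsb
    ideal = params.v_min + lsb * np.arange(1, n_levels)
    if params.perturb_sigma > 0:
        rng = np.random.default_rng(params.seed)
        t = ideal + rng.normal(0.0, params.perturb_sigma * lsb, n_levels - 1)
        t = np.sort(t)
        # enforce strict monotonicity against (measure-zero) ties
        eps = lsb * 1e-12
        for i in range(1, len(t)):
            if t[i] <= t[i - 1]:
                t[i] = t[i - 1] + eps
    else:
        t = ideal
    return ReferenceLadder(
        thresholds=t, lsb=lsb, v_min=params.v_min, v_max=params.v_max,
        n_bits=params.n_bits,
    )


def quantize(signal: np.ndarray, ladder: ReferenceLadder) -> np.ndarray:
    """Thermometer-to-binary: code = number of thresholds strictly below the
    sample.  Codes lie in [0, 2^n - 1]; out-of-range inputs saturate."""
    x = np.asarray(signal, dtype=float)
    return np.searchsorted(ladder.thresholds, x, side="left").astype(np.int64)


def codes_to_voltage(codes: np.ndarray, ladder: ReferenceLadder) -> np.ndarray:
    """Mid-tread reconstruction v = v_min + (code + 1/2) * lsb (ideal LSB)."""
    c = np.asarray(codes)
    if np.any((c < 0) | (c > 2**ladder.n_bits - 1)):
        raise ValueError("codes out of range")
    return ladder.v_min + (c + 0.5) * ladder.lsb


def inl_dnl(ladder: ReferenceLadder) -> tuple[np.ndarray, np.ndarray]:
    """INL_i = (t_i - t_i_ideal)/lsb (2^n - 1 entries) and
    DNL_i = (t_{i+1} - t_i)/lsb - 1 (2^n - 2 entries)."""
    ideal = ladder.v_min + ladder.lsb * np.arange(1, 2**ladder.n_bits)
    inl = (ladder.thresholds - ideal) / ladder.lsb
    dnl = np.diff(ladder.thresholds) / ladder.lsb - 1.0
    return inl, dnl


def adc_chain(signal: np.ndarray, fs: float, params: AdcParams) -> np.ndarray:
    """Full behavioral converter: thermal noise, sample/hold, perturbed-ladder
    quantization, mid-tread reconstruction.  Deterministic under params.seed
    (ladder and noise draws both derive from it)."""
    x = np.asarray(signal, dtype=float)
    if fs <= 0:
        raise ValueError("fs must be positive")
    if params.noise_floor > 0:
        x = x + white_noise(len(x), params.noise_floor, fs, params.seed + 1)
    ladder = build_reference_ladder(params)
    clipped = np.count_nonzero((x < params.v_min) | (x > params.v_max))
    if clipped > 0.01 * len(x):
        warnings.warn(
            f"persistent saturation: {clipped}/{len(x)} samples outside "
            f"[{params.v_min:g}, {params.v_max:g}] V",
            RuntimeWarning,
            stacklevel=2,
        )
    return codes_to_voltage(quantize(x, ladder), ladder)


def ideal_snr_db(n_bits: int) -> float:
    """Quantization-noise SNR of a full-scale sine: 6.02 n + 1.76 dB."""
    return 6.02 * n_bits + 1.76
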