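"""Single-tone linearity characterization and waveform-error metrics.

SNR, THD, SNDR, SFDR and ENOB are estimated from the FFT of a single-tone
record.  Coherent records (an integer number of tone periods) are analyzed
with a rectangular window and single-bin clusters; non-coherent records fall
back to a 4-term Blackman-Harris window with 7-bin clusters around the
fundamental, its harmonics and DC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["ToneMetrics", "tone_metrics", "welch_psd", "nrmse", "enob_from_sndr"]


@dataclass(frozen=True)
class ToneMetrics:
    snr_db: float
    thd_db: float
    sndr_db: float
    sfdr_db: float
    enob_bits: float
    fundamental_amp: float
    f0: float


def enob_from_sndr(sndr_db: float) -> float:
    """Effective number of bits: (SNDR - 1.76) / 6.02."""
    return (sndr_db - 1.76) / 6.02


def _cluster(idx: int, half: int, n_bins: int) -> np.ndarray:
    lo = max(idx - half, 0)
    hi = min(idx + half, n_bins - 1)
    return np.arange(lo, hi + 1)


def _alias_bin(f: float, fs: float, n_bins: int, n: int) -> int:
    """Bin index of frequency f after folding into [0, fs/2]."""
    f = f % fs
    if f > fs / 2.0:
        f = fs - f
    return min(int(round(f * n / fs)), n_bins - 1)


def tone_metrics(
    signal: np.ndarray,
    fs: float,
    f0: float,
    n_harmonics: int = 10,
) -> ToneMetrics:
    """Estimate SNR/THD/SNDR/SFDR/ENOB of a single-tone record.

    Harmonic power is collected at k*f0 for k = 2..n_harmonics+1 (folded
    across Nyquist); noise power is the residual after removing DC, the
    fundamental and the harmonics.
    """
    x = np.asarray(signal, dtype=float)
    n = len(x)
    if n < 16:
        raise ValueError("record too short")
    if not 0 < f0 < fs / 2.0:
        raise ValueError("f0 must lie in (0, fs/2)")
    cycles = f0 * n / fs
    if cycles < 4:
        raise ValueError("f0 not resolvable: fewer than 4 tone periods in the record")
    coherent = abs(cycles - round(cycles)) < 1e-3
    if coherent:
        w = np.ones(n)
        half = 1
    else:
        w = sps.get_window("blackmanharris", n)
        half = 3
    spec = np.fft.rfft(x * w)
    p = np.abs(spec) ** 2
    n_bins = len(p)

    k0 = _alias_bin(f0, fs, n_bins, n)
    dc_bins = _cluster(0, half, n_bins)
    fund_bins = _cluster(k0, half, n_bins)
    harm_bins: list[np.ndarray] = []
    used = set(dc_bins) | set(fund_bins)
    for k in range(2, n_harmonics + 2):
        kb = _alias_bin(k * f0, fs, n_bins, n)
        cl = _cluster(kb, half, n_bins)
        cl = np.array([b for b in cl if b not in used], dtype=int)
        if cl.size:
            harm_bins.append(cl)
            used.update(cl)

    p_dc = p[dc_bins].sum()
    p_fund = p[fund_bins].sum()
    p_harm = sum(p[cl].sum() for cl in harm_bins)
    p_total = p.sum()
    # floors relative to total power: keep log ratios finite without overflow
    floor = max(p_total, 1.0) * 1e-30
    p_noise = max(p_total - p_dc - p_fund - p_harm, floor)
    p_fund = max(p_fund, floor)
    p_harm = max(p_harm, floor)

    # largest spur: max clustered power outside DC and the fundamental
    mask = np.ones(n_bins, dtype=bool)
    mask[dc_bins] = False
    mask[fund_bins] = False
    if mask.any():
        spur_center = int(np.argmax(np.where(mask, p, 0.0)))
        spur_bins = _cluster(spur_center, half, n_bins)
        spur_bins = spur_bins[~np.isin(spur_bins, np.concatenate([dc_bins, fund_bins]))]
        p_spur = max(p[spur_bins].sum(), floor)
    else:
        p_spur = floor

    s1 = w.sum()
    amp = 2.0 * math.sqrt(p_fund) / s1
    snr = 10.0 * math.log10(p_fund / p_noise)
    thd = 10.0 * math.log10(p_harm / p_fund)
    sndr = 10.0 * math.log10(p_fund / (p_noise + p_harm))
    sfdr = 10.0 * math.log10(p_fund / p_spur)
    return ToneMetrics(
        snr_db=snr,
        thd_db=thd,
        sndr_db=sndr,
        sfdr_db=sfdr,
        enob_bits=enob_from_sndr(sndr),
        fundamental_amp=amp,
        f0=f0,
    )


def welch_psd(
    signal: np.ndarray, fs: float, segment_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Welch PSD estimate (V^2/Hz)."""
    x = np.asarray(signal, dtype=float)
    if segment_length > len(x):
        raise ValueError("segment_length exceeds the record length")
    return sps.welch(x, fs=fs, nperseg=segment_length)


def nrmse(reference: np.ndarray, test: np.ndarray) -> float:
    """RMS(reference - test) normalized by the reference peak-to-peak range."""
    r = np.asarray(reference, dtype=float)
    t = np.asarray(test, dtype=float)
    if r.shape != t.shape:
        raise ValueError("waveforms must have equal shape")
    rng = r.max() - r.min()
    if rng <= 0:
        raise ValueError("flat reference waveform: NRMSE undefined")
    return float(np.sqrt(np.mean((r - t) ** 2)) / rng)
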