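"""Behavioral models of the analog front end of a neural recording channel.

Two capacitive-feedback gain stages are modeled: a low-noise amplifier (LNA,
Harrison topology, mid-band gain Cin/Cf with a pseudo-resistor high-pass) and
a programmable-gain amplifier (PGA, gain C1/C2, first-order low-pass).  Each
stage is a linear closed-loop transfer function plus two non-ideal additions:

* a sample-synchronous slew/settling error injection controlled by the
  stage's gain-bandwidth product (GBW) and slew rate (SR), and
* a white Gaussian input-referred noise source with a prescribed one-sided
  PSD floor (thermal noise dominates in the 200-3000 Hz spike band, so no
  1/f component is modeled).

All quantities are SI (farad, ohm, siemens-equivalent A/V, hertz, volt).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional

import numpy as np
from scipy import signal as sps

__all__ = [
    "StageRole",
    "AmplifierParams",
    "DerivedAmpQuantities",
    "SlewErrorBreakdown",
    "lna_closed_loop_tf",
    "lna_open_loop_tf",
    "pga_closed_loop_tf",
    "compute_derived",
    "slew_error",
    "white_noise",
    "process_amplifier",
    "gm_for_gbw",
    "sr_from_ids",
    "default_lna",
    "default_pga",
]


class StageRole(str, Enum):
    LNA = "LNA"
    PGA = "PGA"


# Noise-floor defaults place the single-tone SNR of each stage (100 uV tone
# into the LNA, 10 mV into the PGA, measured over a 24 kHz Nyquist band) near
# 32.4 dB and 33.1 dB respectively -- representative front-end noise levels
# for a 100 uV extracellular test tone.
_LNA_NOISE_FLOOR = 1.187e-16  # V^2/Hz, input-referred
_PGA_NOISE_FLOOR = 1.022e-12  # V^2/Hz, input-referred at the PGA input


@dataclass
class AmplifierParams:
    """One amplifier stage: capacitances, transconductance, speed limits, noise.

    For the PGA the fields map onto its conventional symbols as
    Cin -> C1, Cf -> C2, Rf -> R1.  ``SR=None`` disables slew limiting (the
    stage is then purely linear apart from its noise source).  ``GBW`` may be
    given instead of ``Gm`` (or both, in which case they must agree with
    GBW = Gm / (2 pi Cl) to 1 %).  ``Ids`` optionally pins the SR/GBW ratio
    through SR/GBW = 4 pi Ids / Gm.
    """

    Cin: float
    Cf: float
    Cl: float
    role: StageRole = StageRole.LNA
    Cp: float = 0.0
    Rf: float = 10e9
    Gm: Optional[float] = None
    Ro: float = 100e6
    GBW: Optional[float] = None
    SR: Optional[float] = None
    Ids: Optional[float] = None
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Cin", "Cf", "Cl", "Rf", "Ro"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.Cp < 0:
            raise ValueError("Cp must be non-negative")
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be non-negative")
        if self.Gm is None and self.GBW is None:
            raise ValueError("one of Gm or GBW is required")
        if self.Gm is None:
            self.Gm = 2.0 * math.pi * self.GBW * self.Cl
        if self.Gm <= 0:
            raise ValueError("Gm must be positive")
        gbw_implied = self.Gm / (2.0 * math.pi * self.Cl)
        if self.GBW is None:
            self.GBW = gbw_implied
        elif abs(self.GBW - gbw_implied) > 0.01 * gbw_implied:
            raise ValueError(
                f"inconsistent GBW={self.GBW:g} vs Gm/(2 pi Cl)={gbw_implied:g}"
            )
        if self.SR is not None and self.SR <= 0:
            raise ValueError("SR must be positive (or None for no slew limit)")
        if self.Ids is not None:
            if self.SR is None:
                raise ValueError("Ids given without SR")
            ratio = 4.0 * math.pi * self.Ids / self.Gm
            if abs(self.SR / self.GBW - ratio) > 0.01 * ratio:
                raise ValueError("SR/GBW inconsistent with 4 pi Ids / Gm")

    def scaled_speed(self, factor: float) -> "AmplifierParams":
        """Return a copy with (GBW, SR) scaled by ``factor`` at fixed SR/GBW.

        Gm is rescaled alongside GBW to keep GBW = Gm/(2 pi Cl); Ids (if any)
        follows so that SR/GBW = 4 pi Ids/Gm still holds.
        """
        if factor <= 0:
            raise ValueError("factor must be positive")
        return replace(
            self,
            Gm=self.Gm * factor,
            GBW=self.GBW * factor,
            SR=None if self.SR is None else self.SR * factor,
            Ids=None if self.Ids is None else self.Ids * factor,
        )


@dataclass(frozen=True)
class DerivedAmpQuantities:
    beta: float            # mid-band feedback coefficient Cf/(Cin+Cp+Cf)
    CL_eff: float          # equivalent load Cl + (1-beta) Cf
    tau: float             # integration time constant 2 pi Cin Cl / (Gm Cf)
    midband_gain: float    # Cin/Cf


@dataclass(frozen=True)
class SlewErrorBreakdown:
    case_id: int           # 1: fully slewing, 2: slew then settle, 3: linear
    slope: float           # V/s, |vin|/tau
    t_sl: float            # s, slewing time
    t_lin: float           # s, linear settling time within the half-sample
    error: float           # V, settling error magnitude


def _validate_role(params: AmplifierParams, role: StageRole) -> None:
    if params.role != role:
        raise ValueError(f"expected a {role.value} parameter set, got {params.role.value}")


def compute_derived(params: AmplifierParams) -> DerivedAmpQuantities:
    beta = params.Cf / (params.Cin + params.Cp + params.Cf)
    cl_eff = params.Cl + (1.0 - beta) * params.Cf
    tau = 2.0 * math.pi * params.Cin * params.Cl / (params.Gm * params.Cf)
    return DerivedAmpQuantities(
        beta=beta,
        CL_eff=cl_eff,
        tau=tau,
        midband_gain=params.Cin / params.Cf,
    )


def lna_closed_loop_tf(params: AmplifierParams) -> sps.TransferFunction:
    """Closed-loop LNA response: inverting mid-band gain Cin/Cf, a
    pseudo-resistor high-pass zero at DC and a GBW-set low-pass pole.

    H(s) = (Cin/Cf) * (-s Rf Cf / (1 + s Rf Cf)) * 1 / (1 + s CL1/(Gm beta))
    with beta at its mid-band limit Cf/(Cin+Cp+Cf).
    """
    _validate_role(params, StageRole.LNA)
    d = compute_derived(params)
    g = d.midband_gain
    hp = params.Rf * params.Cf
    lp = d.CL_eff / (params.Gm * d.beta)
    num = [-g * hp, 0.0]
    den = np.polymul([hp, 1.0], [lp, 1.0])
    return sps.TransferFunction(num, den)


def lna_open_loop_tf(params: AmplifierParams) -> sps.TransferFunction:
    """Open-loop LNA gain Gm1 Ro1 beta / (1 + s Ro1 CL1); valid for Rf >> Ro."""
    _validate_role(params, StageRole.LNA)
    d = compute_derived(params)
    a0 = params.Gm * params.Ro * d.beta
    return sps.TransferFunction([a0], [params.Ro * d.CL_eff, 1.0])


def pga_closed_loop_tf(params: AmplifierParams) -> sps.TransferFunction:
    """Closed-loop PGA response -(C1/C2) / (1 + s CL2/(Gm2 betaP))."""
    _validate_role(params, StageRole.PGA)
    d = compute_derived(params)
    lp = d.CL_eff / (params.Gm * d.beta)
    return sps.TransferFunction([-d.midband_gain], [lp, 1.0])


def gm_for_gbw(gbw_hz: float, cl_farad: float) -> float:
    """Transconductance needed for a target GBW into load Cl: Gm = 2 pi GBW Cl."""
    if gbw_hz <= 0 or cl_farad <= 0:
        raise ValueError("gbw_hz and cl_farad must be positive")
    return 2.0 * math.pi * gbw_hz * cl_farad


def sr_from_ids(ids_amp: float, cl_farad: float) -> float:
    """Slew rate of a class-A OTA output: SR = 2 Ids / Cl."""
    if ids_amp <= 0 or cl_farad <= 0:
        raise ValueError("ids_amp and cl_farad must be positive")
    return 2.0 * ids_amp / cl_farad


def slew_error(vin_abs: float, params: AmplifierParams, Ts: float) -> SlewErrorBreakdown:
    """Three-case slew/settling error for one voltage step of magnitude vin_abs.

    The required slewing time is t_sl = |vin|/SR - tau.

    Case 1 (|slope| > SR, t_sl >= Ts/2): the stage slews for the entire
    half-sample and advances only SR*Ts/2, so error = |vin| - SR*(Ts/2).
    Case 2 (|slope| > SR, t_sl < Ts/2): slewing completes, then exponential
    settling for t_lin = Ts/2 - t_sl: error = (|vin| - SR*t_sl) exp(-t_lin/tau).
    Case 3 (|slope| <= SR): purely linear settling,
    error = |vin| exp(-Ts/(2 tau)).

    The three branches are continuous in |vin|; ``SR=None`` is treated as an
    infinite slew rate (case 3 always).  Error magnitudes are clamped at
    zero from below.
    """
    if vin_abs < 0:
        raise ValueError("vin_abs must be non-negative")
    if Ts <= 0:
        raise ValueError("Ts must be positive")
    tau = compute_derived(params).tau
    sr = params.SR
    slope = vin_abs / tau
    if sr is not None and sr <= 0:
        raise ValueError("SR must be positive")
    if sr is None or slope <= sr:
        err = vin_abs * math.exp(-Ts / (2.0 * tau))
        return SlewErrorBreakdown(3, slope, 0.0, Ts / 2.0, max(err, 0.0))
    t_sl = max(vin_abs / sr - tau, 0.0)
    if t_sl >= Ts / 2.0:
        err = vin_abs - sr * (Ts / 2.0)
        return SlewErrorBreakdown(1, slope, t_sl, 0.0, max(err, 0.0))
    t_lin = Ts / 2.0 - t_sl
    err = (vin_abs - sr * t_sl) * math.exp(-t_lin / tau)
    return SlewErrorBreakdown(2, slope, t_sl, t_lin, max(err, 0.0))


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not args else args[0]


@_njit(cache=True)
def _inject_slew(y_lin: np.ndarray, sr: float, tau: float, Ts: float) -> np.ndarray:
    """Sample-synchronous error injection with output memory.

    At each sample the stage must close the residual step dv between the
    linear-response target and its own previous output; the three-case
    slew/settling error of that step is subtracted in the direction of the
    step, so lag accumulates during fast excursions exactly as a slewing
    OTA lags a fast input.
    """
    n = y_lin.shape[0]
    y = np.empty_like(y_lin)
    y[0] = y_lin[0]
    half_ts = Ts / 2.0
    lin_decay = math.exp(-half_ts / tau)
    for i in range(1, n):
        dv = y_lin[i] - y[i - 1]
        adv = abs(dv)
        if adv / tau <= sr:
            err = adv * lin_decay
        else:
            t_sl = adv / sr - tau
            if t_sl < 0.0:
                t_sl = 0.0
            if t_sl >= half_ts:
                err = adv - sr * half_ts
            else:
                err = (adv - sr * t_sl) * math.exp(-(half_ts - t_sl) / tau)
        if err < 0.0:
            err = 0.0
        elif err > adv:
            err = adv
        y[i] = y_lin[i] - err if dv >= 0.0 else y_lin[i] + err
    return y


def white_noise(n_samples: int, noise_floor: float, fs: float, seed: int) -> np.ndarray:
    """Zero-mean Gaussian series whose one-sided PSD floor equals noise_floor.

    Per-sample variance sigma^2 = noise_floor * fs / 2.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if noise_floor < 0:
        raise ValueError("noise_floor must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(noise_floor * fs / 2.0)
    return rng.normal(0.0, sigma, n_samples) if sigma > 0 else np.zeros(n_samples)


def _discretize(tf: sps.TransferFunction, fs: float) -> tuple[np.ndarray, np.ndarray]:
    b, a = sps.bilinear(tf.num, tf.den, fs)
    return b, a


def process_amplifier(
    signal: np.ndarray,
    fs: float,
    params: AmplifierParams,
    seed: int = 0,
) -> np.ndarray:
    """Run one stage: input-referred noise, bilinear-discretized closed-loop
    filter, then sample-synchronous slew/settling error injection.

    The error magnitude is evaluated on the output-referred residual step
    between the linear-response target and the stage's previous output and
    subtracted in the direction of that step, so the output lags the ideal
    response and the lag accumulates during fast excursions; with ``SR=None``
    and ``noise_floor=0`` the output equals the pure linear filter response.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if fs <= 0:
        raise ValueError("fs must be positive")
    d = compute_derived(params)
    f_pole = params.Gm * d.beta / (2.0 * math.pi * d.CL_eff)
    if f_pole > fs / 2.0:
        warnings.warn(
            f"closed-loop pole {f_pole:.3g} Hz above Nyquist {fs / 2:.3g} Hz; "
            "the stage's own dynamics alias onto the simulation grid",
            RuntimeWarning,
            stacklevel=2,
        )
    if params.noise_floor > 0:
        x = x + white_noise(len(x), params.noise_floor, fs, seed)
    tf = (
        lna_closed_loop_tf(params)
        if params.role == StageRole.LNA
        else pga_closed_loop_tf(params)
    )
    b, a = _discretize(tf, fs)
    y_lin = sps.lfilter(b, a, x)
    if params.SR is None:
        return y_lin
    # SR and tau are referred to the stage output node
    return _inject_slew(y_lin, params.SR, d.tau, 1.0 / fs)


def default_lna(noise: bool = True) -> AmplifierParams:
    """40 dB LNA: Cin=20 pF, Cf=200 fF, Cl=1 pF, GBW=10 MHz (Gm=62.8 uA/V)."""
    return AmplifierParams(
        Cin=20e-12,
        Cf=200e-15,
        Cl=1e-12,
        role=StageRole.LNA,
        Rf=10e9,
        GBW=10e6,
        noise_floor=_LNA_NOISE_FLOOR if noise else 0.0,
    )


def default_pga(noise: bool = True) -> AmplifierParams:
    """20 dB PGA: C1=2 pF, C2=200 fF, Cl=1 pF, GBW=5 MHz."""
    return AmplifierParams(
        Cin=2e-12,
        Cf=200e-15,
        Cl=1e-12,
        role=StageRole.PGA,
        Rf=10e9,
        GBW=5e6,
        noise_floor=_PGA_NOISE_FLOOR if noise else 0.0,
    )
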