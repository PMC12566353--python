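"""Signal, ground-truth and configuration I/O.

Signals travel as raw little-endian float64 binaries with a JSON sidecar
(``<name>.json`` next to the data file) recording the sampling rate, units
and sample count; small fixtures may use plain text (one sample per line).
Ground truth is a two-column CSV (time_s, unit_label).  Stage configuration
files are flat YAML sections named after the stages, with AmplifierParams /
AdcParams field names in SI units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adc import AdcParams
from .frontend import AmplifierParams, StageRole

__all__ = [
    "write_signal",
    "read_signal",
    "write_truth",
    "read_truth",
    "load_config",
]


def write_signal(path: str | Path, signal: np.ndarray, fs: float,
                 units: str = "V", channel: int = 0) -> None:
    path = Path(path)
    x = np.asarray(signal, dtype="<f8")
    if path.suffix in (".txt", ".csv"):
        np.savetxt(path, x)
    else:
        x.tofile(path)
    sidecar = {
        "fs_hz": float(fs),
        "units": units,
        "n_samples": int(len(x)),
        "channel": int(channel),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_signal(path: str | Path) -> tuple[np.ndarray, float]:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if path.suffix in (".txt", ".csv"):
        x = np.loadtxt(path, dtype=float)
    else:
        x = np.fromfile(path, dtype="<f8")
    if len(x) != meta["n_samples"]:
        raise ValueError(
            f"sidecar says {meta['n_samples']} samples, file holds {len(x)}"
        )
    return x, float(meta["fs_hz"])


def write_truth(path: str | Path, times_s: np.ndarray, labels: np.ndarray) -> None:
    pd.DataFrame({"time_s": times_s, "unit_label": labels}).to_csv(path, index=False)


def read_truth(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(float), df["unit_label"].to_numpy(int)


_AMP_FIELDS = {"Cin", "Cf", "Cl", "Cp", "Rf", "Gm", "Ro", "GBW", "SR", "Ids",
               "noise_floor"}
_ADC_FIELDS = {"n_bits", "v_min", "v_max", "perturb_sigma", "noise_floor", "seed"}


def load_config(path: str | Path) -> dict:
    """Read a flat YAML config with optional ``lna``, ``pga`` and ``adc``
    sections into parameter objects."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    for key, role in (("lna", StageRole.LNA), ("pga", StageRole.PGA)):
        if key in raw:
            sec = {k: v for k, v in raw[key].items() if k in _AMP_FIELDS}
            out[key] = AmplifierParams(role=role, **sec)
    if "adc" in raw:
        sec = {k: v for k, v in raw["adc"].items() if k in _ADC_FIELDS}
        out["adc"] = AdcParams(**sec)
    return out
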