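"""Open on-disk formats: transient containers, config files, CSV tables.

A transient container is a raw block of little-endian 32-bit float samples
plus a JSON metadata sidecar (``<path>.json``) carrying the format version,
acquisition parameters and, for simulated data, the generating truth
records.  Round trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .instrument import GAS_PRESETS, DEFAULT_INSTRUMENT, GasModel, InstrumentModel
from .simulate import Transient

__all__ = [
    "FORMAT_NAME",
    "FORMAT_VERSION",
    "write_transient",
    "read_transient",
    "read_config",
    "instrument_from_config",
    "gas_from_config",
    "centroids_to_frame",
    "traces_to_frame",
    "ions_to_frame",
]

FORMAT_NAME = "orbichase-transient"
FORMAT_VERSION = 1
_SAMPLE_DTYPE = "<f4"


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def _sanitize(obj):
    """JSON-safe copy: numpy scalars -> python, NaN -> None."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    return obj


def write_transient(
    transient: Transient,
    path: str | Path,
    instrument: InstrumentModel | None = None,
) -> None:
    """Write samples as little-endian float32 plus a JSON metadata sidecar."""
    path = Path(path)
    samples = np.asarray(transient.samples)
    if not np.all(np.isfinite(samples)):
        raise ValueError("refusing to write non-finite samples")
    samples.astype(_SAMPLE_DTYPE).tofile(path)
    meta = {
        "format": FORMAT_NAME,
        "format_version": FORMAT_VERSION,
        "dtype": _SAMPLE_DTYPE,
        "sample_rate_hz": transient.sample_rate_hz,
        "duration_s": transient.duration_s,
        "n_samples": transient.n_samples,
        "seed": transient.seed,
        "truth": _sanitize(transient.truth),
    }
    if instrument is not None:
        meta["instrument"] = dataclasses.asdict(instrument)
    _sidecar(path).write_text(
        json.dumps(meta, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_transient(path: str | Path) -> Transient:
    """Read a transient container; raises on version or sample-count mismatch."""
    path = Path(path)
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text(encoding="utf-8"))
    if meta.get("format") != FORMAT_NAME or meta.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported container format "
            f"{meta.get('format')!r} v{meta.get('format_version')!r}; "
            f"expected {FORMAT_NAME!r} v{FORMAT_VERSION}"
        )
    samples = np.fromfile(path, dtype=meta.get("dtype", _SAMPLE_DTYPE))
    if len(samples) != meta["n_samples"]:
        raise ValueError(
            f"truncated sample block: expected {meta['n_samples']} samples, "
            f"found {len(samples)}"
        )
    if not np.all(np.isfinite(samples)):
        raise ValueError("container holds non-finite samples")
    return Transient(
        samples=samples,
        sample_rate_hz=meta["sample_rate_hz"],
        duration_s=meta["duration_s"],
        seed=meta.get("seed"),
        truth=meta.get("truth"),
    )


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` text config with dotted namespaces."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


_INSTRUMENT_FIELDS = {
    "freq_coeff_mhz": float,
    "dist_per_osc_mm": float,
    "sample_rate_hz": float,
    "zero_pad_factor": int,
    "charge_gain": float,
    "proton_mass_da": float,
}

_GAS_FIELDS = {
    "species": str,
    "gas_mass_da": float,
    "gas_radius_m": float,
    "gauge_pressure_mbar": float,
    "trap_pressure_multiplier": float,
    "gauge_gas_correction": float,
    "temperature_k": float,
}


def instrument_from_config(config: dict[str, str]) -> InstrumentModel:
    """Build an InstrumentModel from ``instrument.*`` keys (defaults fill the rest)."""
    kwargs = {
        name: cast(config[f"instrument.{name}"])
        for name, cast in _INSTRUMENT_FIELDS.items()
        if f"instrument.{name}" in config
    }
    return InstrumentModel(**kwargs)


def gas_from_config(config: dict[str, str], preset: str | None = None) -> GasModel:
    """Build a GasModel from ``gas.*`` keys, optionally starting from a preset."""
    preset = config.get("gas.preset", preset)
    base = GAS_PRESETS[preset] if preset else GasModel()
    kwargs = dataclasses.asdict(base)
    for name, cast in _GAS_FIELDS.items():
        if f"gas.{name}" in config:
            kwargs[name] = cast(config[f"gas.{name}"])
    return GasModel(**kwargs)


def centroids_to_frame(centroids, scan_id: int = 0) -> pd.DataFrame:
    """Centroid table with the standard column order."""
    return pd.DataFrame(
        [
            {
                "scan_id": scan_id,
                "segment_index": c.segment_index,
                "mz": c.mz,
                "frequency_hz": c.frequency_hz,
                "intensity": c.intensity,
                "fwhm_th": c.fwhm_th,
                "snr": c.snr,
            }
            for c in centroids
        ],
        columns=["scan_id", "segment_index", "mz", "frequency_hz", "intensity", "fwhm_th", "snr"],
    )


def traces_to_frame(traces, scan_id: int = 0) -> pd.DataFrame:
    """Long-format trace table: one row per (trace, segment)."""
    rows = []
    for tid, tr in enumerate(traces):
        for c in tr.centroids:
            rows.append(
                {
                    "trace_id": tid,
                    "scan_id": scan_id,
                    "segment_index": c.segment_index,
                    "mz": c.mz,
                    "intensity": c.intensity,
                    "classification": tr.classification,
                    "assigned_charge": tr.assigned_charge,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "trace_id", "scan_id", "segment_index", "mz",
            "intensity", "classification", "assigned_charge",
        ],
    )


def ions_to_frame(ions, scan_ids=None, trace_ids=None) -> pd.DataFrame:
    """CDMS ion table."""
    rows = []
    for i, ion in enumerate(ions):
        rows.append(
            {
                "scan_id": scan_ids[i] if scan_ids is not None else i,
                "trace_id": trace_ids[i] if trace_ids is not None else None,
                "mz": ion.mz,
                "intensity": ion.intensity,
                "charge": ion.charge,
                "mass": ion.mass_da,
                "source": ion.source,
                "flags": ";".join(ion.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["scan_id", "trace_id", "mz", "intensity", "charge", "mass", "source", "flags"],
    )
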