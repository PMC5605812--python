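"""Readers and writers for pipeline artifacts (CSV, JSON, YAML, TIFF)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hkspeckle.fitting import AmplitudeHistogram, FitResult
from hkspeckle.phantom import Phantom, PhantomSpec
from hkspeckle.simulate import AcousticConfig, EnvelopeImage

__all__ = [
    "write_phantom",
    "read_phantom",
    "write_histogram_csv",
    "read_histogram_csv",
    "write_fit_json",
    "write_envelope",
    "read_amplitudes",
    "write_manifest",
    "load_acoustic_config",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 losslessly


def write_phantom(phantom: Phantom, spec: PhantomSpec, path: Path) -> None:
    """Write positions/strengths CSV plus a JSON sidecar with the full spec."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "x_m": phantom.positions[:, 0],
            "y_m": phantom.positions[:, 1],
            "z_m": phantom.positions[:, 2],
            "strength": phantom.strengths,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = path.with_suffix(".spec.json")
    sidecar.write_text(json.dumps(spec.to_dict(), indent=2, sort_keys=True))


def read_phantom(path: Path) -> Phantom:
    df = pd.read_csv(path)
    return Phantom(
        positions=df[["x_m", "y_m", "z_m"]].to_numpy(),
        strengths=df["strength"].to_numpy(),
    )


def write_histogram_csv(hist: AmplitudeHistogram, path: Path) -> None:
    df = pd.DataFrame(
        {
            "edge_low": hist.edges[:-1],
            "edge_high": hist.edges[1:],
            "count": hist.counts,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_histogram_csv(path: Path) -> AmplitudeHistogram:
    df = pd.read_csv(path)
    edges = np.append(df["edge_low"].to_numpy(), df["edge_high"].to_numpy()[-1])
    return AmplitudeHistogram(edges=edges, counts=df["count"].to_numpy())


def write_fit_json(fits: dict[str, FitResult], path: Path, comparison=None) -> None:
    payload = {name: json.loads(f.to_json()) for name, f in fits.items()}
    if comparison is not None:
        payload["comparison"] = {
            "okrr_label": comparison.okrr_label,
            "okrr_model": comparison.okrr.model,
            "rel_diff_pct": comparison.rel_diff_pct,
            "bic_hk": comparison.hk.bic,
            "bic_okrr": comparison.okrr.bic,
        }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_envelope(img: EnvelopeImage, path: Path, tiff: bool = False) -> None:
    """Envelope amplitudes as CSV; optionally a single-channel TIFF alongside."""
    path = Path(path)
    np.savetxt(path, img.amplitudes, delimiter=",", fmt=_FLOAT_FMT)
    if tiff:
        import tifffile

        tifffile.imwrite(path.with_suffix(".tif"), img.amplitudes.astype(np.float32))


def read_amplitudes(path: Path) -> np.ndarray:
    """Read a one-column (or whitespace/comma separated) file of amplitudes."""
    arr = np.loadtxt(path, delimiter=",", ndmin=1)
    return np.asarray(arr, float).ravel()


def write_manifest(path: Path, command: str, config: dict) -> None:
    """Record everything needed to re-run a command bit-identically."""
    payload = {"command": command, "config": _jsonable(config)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def load_acoustic_config(path: Path) -> AcousticConfig:
    """AcousticConfig from a YAML file mirroring its field names."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return AcousticConfig(**data)
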