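"""Plain-text trace store: one CSV + JSON sidecar per sweep, plus a manifest.

Layout of a trace directory:

* ``manifest.json``   experiment name, format version, sweep file list, design
* ``sweep_0000.csv``  columns ``time_ms,voltage_mV,current_pA``
* ``sweep_0000.json`` sweep metadata (protocol, condition, seed, ...)

Floats are written with 17 significant digits so a read/write round trip is
bit-exact.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TraceFormatError
from .protocols import VoltageProtocol
from .simulate import Experiment, Sweep

__all__ = ["write_traces", "read_traces"]

FORMAT_VERSION = "1.0"
_COLUMNS = ["time_ms", "voltage_mV", "current_pA"]


def write_traces(exp: Experiment, directory) -> Path:
    """Write an experiment to ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sw in enumerate(exp.sweeps):
        stem = f"sweep_{i:04d}"
        _write_sweep_csv(sw, directory / f"{stem}.csv")
        sidecar = {
            "meta": _jsonable(sw.meta),
            "protocol": {
                "name": sw.protocol.name,
                "segments": [list(seg) for seg in sw.protocol.segments],
                "sample_interval": sw.protocol.sample_interval,
            },
            "n_samples": int(sw.time.size),
        }
        (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
        entries.append({"csv": f"{stem}.csv", "sidecar": f"{stem}.json"})
    manifest = {
        "format_version": FORMAT_VERSION,
        "name": exp.name,
        "n_sweeps": len(exp.sweeps),
        "sweeps": entries,
        "design": exp.design.to_dict(orient="list"),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def read_traces(directory) -> Experiment:
    """Read an experiment back; inverse of :func:`write_traces`."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise TraceFormatError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    sweeps = []
    for entry in manifest["sweeps"]:
        csv_path = directory / entry["csv"]
        sidecar_path = directory / entry["sidecar"]
        if not csv_path.exists():
            raise TraceFormatError(f"manifest lists absent file: {csv_path}")
        if not sidecar_path.exists():
            raise TraceFormatError(f"missing sidecar: {sidecar_path}")
        sidecar = json.loads(sidecar_path.read_text())
        table = _read_sweep_csv(csv_path)
        if len(table) != sidecar["n_samples"]:
            raise TraceFormatError(
                f"{csv_path} has {len(table)} samples, sidecar says "
                f"{sidecar['n_samples']}"
            )
        prot = VoltageProtocol(
            name=sidecar["protocol"]["name"],
            segments=tuple(tuple(s) for s in sidecar["protocol"]["segments"]),
            sample_interval=sidecar["protocol"]["sample_interval"],
        )
        sweeps.append(
            Sweep(
                time=table["time_ms"].to_numpy(),
                current=table["current_pA"].to_numpy(),
                voltage=table["voltage_mV"].to_numpy(),
                protocol=prot,
                meta=sidecar["meta"],
            )
        )
    if len(sweeps) != manifest["n_sweeps"]:
        raise TraceFormatError(
            f"{manifest_path}: lists {manifest['n_sweeps']} sweeps, found "
            f"{len(sweeps)}"
        )
    design = pd.DataFrame(manifest["design"])
    return Experiment(sweeps=sweeps, design=design, name=manifest.get("name", ""))


def _write_sweep_csv(sw: Sweep, path: Path) -> None:
    buf = io.StringIO()
    buf.write(",".join(_COLUMNS) + "\n")
    for t, v, i in zip(sw.time.tolist(), sw.voltage.tolist(), sw.current.tolist()):
        buf.write(f"{t!r},{v!r},{i!r}\n")
    path.write_text(buf.getvalue())


def _read_sweep_csv(path: Path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, dtype=float, float_precision="round_trip")
    except Exception as err:  # malformed or truncated file
        raise TraceFormatError(f"cannot parse {path}: {err}") from None
    if list(table.columns) != _COLUMNS:
        raise TraceFormatError(
            f"{path}: expected columns {_COLUMNS}, found {list(table.columns)}"
        )
    if table.isna().any().any():
        raise TraceFormatError(f"{path}: non-numeric or missing values")
    return table


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
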