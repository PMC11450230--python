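"""File round-tripping with provenance headers.

All CSV files are comma separated, UTF-8, '.' decimal, with a mandatory
header row and unit-suffixed column names; lines starting with '#' carry
provenance (package version, seed, config hash) and are ignored by the
readers.  Voltages are stored in mV and concentrations in mol/L at file
level.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .doseresponse import DoseResponseDataset
from .exceptions import ParseError
from .synth import Segment, StepProtocol, TEVCTrace

__all__ = [
    "provenance_header", "config_hash",
    "write_dose_response_csv", "read_dose_response_csv",
    "write_trace_csv", "read_trace_csv",
    "write_json_report", "protocol_to_dict", "protocol_from_dict",
]

DR_COLUMNS = ("conc_M", "dI_A", "replicate")
TRACE_COLUMNS = ("time_s", "current_A")


def config_hash(config: dict | None) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_header(seed=None, config: dict | None = None) -> str:
    return (f"# haksym v{__version__} seed={seed} "
            f"config_sha256={config_hash(config)}")


def _write_csv(path, df: pd.DataFrame, seed, config) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(provenance_header(seed, config) + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path, required: tuple) -> pd.DataFrame:
    path = str(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed file
        line = getattr(exc, "lineno", None)
        raise ParseError(path, line=line, reason=str(exc)) from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(path, line=1, column=missing[0],
                         reason=f"missing required column(s) {missing}")
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(path, line=row + 2, column=col,
                             reason=f"non-numeric value {df[col].iloc[row]!r}")
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna())[0])
            raise ParseError(path, line=row + 2, column=col,
                             reason="missing value")
    return df


def write_dose_response_csv(path, dataset: DoseResponseDataset,
                            seed=None, config: dict | None = None) -> None:
    df = pd.DataFrame({"conc_M": dataset.conc_M, "dI_A": dataset.response,
                       "replicate": dataset.replicate})
    _write_csv(path, df, seed, config)


def read_dose_response_csv(path, substrate: str = "K+") -> DoseResponseDataset:
    df = _read_csv(path, DR_COLUMNS)
    return DoseResponseDataset(conc_M=df["conc_M"].to_numpy(float),
                               response=df["dI_A"].to_numpy(float),
                               replicate=df["replicate"].to_numpy(int),
                               substrate=substrate,
                               meta={"source": str(path)})


def protocol_to_dict(protocol: StepProtocol) -> dict:
    return {"holding_mV": protocol.holding_mV,
            "sampling_hz": protocol.sampling_hz,
            "segments": [{"duration_s": s.duration_s, "conc_M": s.conc_M,
                          "pH": s.pH, "substrate": s.substrate}
                         for s in protocol.segments]}


def protocol_from_dict(d: dict) -> StepProtocol:
    return StepProtocol(holding_mV=d["holding_mV"],
                        sampling_hz=d.get("sampling_hz", 10.0),
                        segments=tuple(Segment(**s) for s in d["segments"]))


def write_trace_csv(path, trace: TEVCTrace, seed=None,
                    config: dict | None = None) -> None:
    """Write a trace as CSV plus a ``<path>.truth.json`` sidecar with the
    generating truth and protocol."""
    df = pd.DataFrame({"time_s": trace.time_s, "current_A": trace.current_A})
    _write_csv(path, df, seed, config)
    sidecar = Path(str(path) + ".truth.json")
    write_json_report(sidecar, {"truth": trace.truth,
                                "protocol": protocol_to_dict(trace.protocol)},
                      seed=seed, config=config)


def read_trace_csv(path) -> TEVCTrace:
    df = _read_csv(path, TRACE_COLUMNS)
    sidecar = Path(str(path) + ".truth.json")
    truth, protocol = {}, None
    if sidecar.exists():
        with open(sidecar) as fh:
            payload = json.load(fh)
        truth = payload.get("truth", {})
        if "protocol" in payload:
            protocol = protocol_from_dict(payload["protocol"])
    if protocol is None:
        t = df["time_s"].to_numpy(float)
        span = float(t[-1] - t[0]) if t.size > 1 else 1.0
        protocol = StepProtocol(holding_mV=float("nan"),
                                segments=(Segment(span + 1e-9, 0.0),),
                                sampling_hz=max(1.0, (t.size - 1) / span))
    return TEVCTrace(time_s=df["time_s"].to_numpy(float),
                     current_A=df["current_A"].to_numpy(float),
                     protocol=protocol, truth=truth)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json_report(path, payload: dict, seed=None,
                      config: dict | None = None) -> None:
    """JSON report with an embedded provenance block."""
    doc = {"provenance": {"package": "haksym", "version": __version__,
                          "seed": seed, "config_sha256": config_hash(config)}}
    doc.update(_jsonable(payload))
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=False)
        fh.write("\n")
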