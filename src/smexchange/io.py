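"""File formats: photon containers, burst/trace tables, image stacks, reports.

Photon records go to an HDF5 container following the photon-HDF5 layout
(``/photon_data`` arrays plus setup metadata) so real ALEX data can be
dropped in, with a columnar-text fallback.  Traces travel as CSV tables
(columns ``trace_id, frame, time_s, donor, acceptor`` and, for synthetic
data, a clearly flagged ``true_state`` column) with a JSON metadata sidecar.
Image stacks are multi-page TIFF.  Analysis reports are JSON documents that
echo every parameter affecting the result, the package version, and the
seed, so a run is reproducible from (inputs, report).

Units everywhere: seconds for time, molar for concentrations, dimensionless
E/S, 0-based frame indices, pixel-center image coordinates.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .burst import Burst, PhotonStream
from .synthetic import FretTrace

__all__ = [
    "SchemaError",
    "write_photon_container",
    "read_photon_container",
    "write_burst_table",
    "read_burst_table",
    "write_trace_table",
    "read_trace_table",
    "write_tiff_stack",
    "read_tiff_stack",
    "write_report",
    "read_report",
]

PACKAGE_VERSION = "0.1.0"


class SchemaError(ValueError):
    """An input file is missing a required group or column."""


# ---------------------------------------------------------------------------
# photon container (photon-HDF5-style)
# ---------------------------------------------------------------------------

_PHOTON_FIELDS = ("timestamps", "excitation_phase", "detection_channel")


def write_photon_container(stream: PhotonStream, path: str | Path) -> None:
    """Write a photon stream to an HDF5 container (photon-HDF5-style layout)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("photon_data")
        g.create_dataset("timestamps", data=stream.timestamps)
        g.create_dataset("excitation_phase", data=stream.excitation_phase)
        g.create_dataset("detection_channel", data=stream.detection_channel)
        setup = f.create_group("setup")
        setup.attrs["alternation_period"] = stream.alternation_period
        setup.attrs["duration"] = stream.duration


def read_photon_container(path: str | Path) -> PhotonStream:
    """Read a photon stream, validating the schema field by field.

    Unsorted timestamps are sorted (all arrays reordered together) with a
    warning; a missing group or dataset raises :class:`SchemaError` naming
    the field rather than returning a silent partial read.
    """
    with h5py.File(path, "r") as f:
        if "photon_data" not in f:
            raise SchemaError("missing group 'photon_data'")
        g = f["photon_data"]
        arrays = {}
        for name in _PHOTON_FIELDS:
            if name not in g:
                raise SchemaError(f"missing dataset 'photon_data/{name}'")
            arrays[name] = g[name][()]
        if "setup" not in f:
            raise SchemaError("missing group 'setup'")
        period = float(f["setup"].attrs.get("alternation_period", 100e-6))
        duration = float(f["setup"].attrs.get("duration", 0.0)) or None

    n = len(arrays["timestamps"])
    for name in _PHOTON_FIELDS[1:]:
        if len(arrays[name]) != n:
            raise SchemaError(f"dataset 'photon_data/{name}' truncated: {len(arrays[name])} != {n}")

    ts = arrays["timestamps"]
    if n and np.any(np.diff(ts) < 0):
        warnings.warn("timestamps were not sorted; sorting on read", stacklevel=2)
        order = np.argsort(ts, kind="stable")
        arrays = {k: v[order] for k, v in arrays.items()}
    return PhotonStream(
        timestamps=arrays["timestamps"],
        excitation_phase=arrays["excitation_phase"],
        detection_channel=arrays["detection_channel"],
        alternation_period=period,
        duration=duration,
    )


# ---------------------------------------------------------------------------
# burst tables
# ---------------------------------------------------------------------------

_BURST_COLUMNS = ["t_start", "t_end", "i_dd", "i_da", "i_aa", "e", "s"]


def write_burst_table(bursts: Sequence[Burst], path: str | Path) -> None:
    """Write bursts to TSV; a ``true_species`` column marks synthetic ground truth."""
    df = pd.DataFrame(
        {
            "t_start": [b.t_start for b in bursts],
            "t_end": [b.t_end for b in bursts],
            "i_dd": [b.i_dd for b in bursts],
            "i_da": [b.i_da for b in bursts],
            "i_aa": [b.i_aa for b in bursts],
            "e": [b.e for b in bursts],
            "s": [b.s for b in bursts],
            "true_species": [b.true_species for b in bursts],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_burst_table(path: str | Path) -> list[Burst]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _BURST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"burst table missing columns: {missing}")
    has_truth = "true_species" in df.columns
    return [
        Burst(
            t_start=row.t_start,
            t_end=row.t_end,
            i_dd=int(row.i_dd),
            i_da=int(row.i_da),
            i_aa=int(row.i_aa),
            e=row.e,
            s=row.s,
            true_species=(
                row.true_species
                if has_truth and isinstance(row.true_species, str)
                else None
            ),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# trace tables
# ---------------------------------------------------------------------------

_TRACE_COLUMNS = ["trace_id", "frame", "time_s", "donor", "acceptor"]


def write_trace_table(
    traces: Sequence[FretTrace], path: str | Path, include_truth: bool = True
) -> None:
    """Write traces to one CSV; per-trace metadata goes to a JSON sidecar."""
    path = Path(path)
    frames = []
    meta = {}
    for i, tr in enumerate(traces):
        df = pd.DataFrame(
            {
                "trace_id": i,
                "frame": np.arange(len(tr)),
                "time_s": tr.time,
                "donor": tr.donor,
                "acceptor": tr.acceptor,
            }
        )
        if include_truth and tr.truth is not None:
            df["true_state"] = tr.truth["frame_state"]  # synthetic ground truth
        frames.append(df)
        meta[str(i)] = {
            "frame_interval": tr.frame_interval,
            "injection_time": tr.injection_time,
            **{k: v for k, v in tr.metadata.items()},
        }
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def read_trace_table(
    path: str | Path, interval_rtol: float = 1e-6
) -> list[FretTrace]:
    """Read traces grouped by ``trace_id``, merging the JSON sidecar.

    A trace whose frame spacing is non-uniform beyond ``interval_rtol`` is
    rejected with an error naming it.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table missing columns: {missing}")
    sidecar = path.with_suffix(".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    traces = []
    for tid, g in df.groupby("trace_id", sort=True):
        g = g.sort_values("frame")
        t = g["time_s"].to_numpy()
        dt = np.diff(t)
        if len(dt):
            if np.max(np.abs(dt - dt[0])) > interval_rtol * max(dt[0], 1e-12):
                raise SchemaError(f"trace {tid}: non-uniform frame interval")
            interval = float(dt[0])
        else:
            interval = float(meta.get(str(tid), {}).get("frame_interval", 0.1))
        m = dict(meta.get(str(tid), {}))
        truth = None
        if "true_state" in g.columns and g["true_state"].notna().all():
            truth = {"frame_state": g["true_state"].to_numpy(dtype=int)}
        traces.append(
            FretTrace(
                time=t,
                donor=g["donor"].to_numpy(),
                acceptor=g["acceptor"].to_numpy(),
                frame_interval=m.pop("frame_interval", interval) or interval,
                injection_time=m.pop("injection_time", None),
                metadata=m,
                truth=truth,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# image stacks and reports
# ---------------------------------------------------------------------------

def write_tiff_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_tiff_stack(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)


def write_report(path: str | Path, result: dict, config: dict, seed: int | None) -> dict:
    """Serialize an analysis report with full parameter provenance."""
    report = {
        "package_version": PACKAGE_VERSION,
        "seed": seed,
        "config": config,
        "result": result,
    }
    Path(path).write_text(json.dumps(report, indent=1, default=_json_default))
    return report


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
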