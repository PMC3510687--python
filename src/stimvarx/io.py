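"""Session container I/O: HDF5 (canonical), delimited text, optional EDF.

HDF5 layout: datasets ``/y`` (d x T) and ``/x`` (T), root attributes
``fs`` and ``channel_names``. CSV: one column per channel plus a
``trigger`` column with a header row; the sampling rate lives in a
``<path>.meta`` sidecar of ``key=value`` lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import SessionData

__all__ = ["read_session", "write_session"]

_TRIGGER_COL = "trigger"


def write_session(session: SessionData, path: str | Path, format: str = "auto") -> None:
    path = Path(path)
    fmt = _resolve_format(path, format)
    if fmt == "hdf5":
        _write_hdf5(session, path)
    elif fmt == "csv":
        _write_csv(session, path)
    else:
        raise ValueError(f"unsupported output format: {fmt}")


def read_session(path: str | Path, format: str = "auto",
                 trigger_channel: str = _TRIGGER_COL) -> SessionData:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _resolve_format(path, format)
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path, trigger_channel)
    raise ValueError(f"unsupported input format: {fmt}")


def _resolve_format(path: Path, format: str) -> str:
    if format != "auto":
        return format
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5", ".hdf"}:
        return "hdf5"
    if suffix in {".csv", ".tsv", ".txt"}:
        return "csv"
    if suffix == ".edf":
        return "edf"
    raise ValueError(f"cannot infer format from suffix {suffix!r}")


def _write_hdf5(session: SessionData, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("y", data=session.y)
        f.create_dataset("x", data=session.x)
        f.attrs["fs"] = session.fs
        f.attrs["channel_names"] = [str(c) for c in session.channel_names]


def _read_hdf5(path: Path) -> SessionData:
    import h5py

    with h5py.File(path, "r") as f:
        if "y" not in f or "x" not in f:
            raise ValueError("HDF5 session must contain datasets /y and /x")
        if "fs" not in f.attrs:
            raise ValueError("HDF5 session missing required attribute 'fs'")
        names = f.attrs.get("channel_names")
        return SessionData(
            y=f["y"][...],
            x=f["x"][...],
            fs=float(f.attrs["fs"]),
            channel_names=None if names is None else [str(c) for c in names],
        )


def _write_csv(session: SessionData, path: Path) -> None:
    df = pd.DataFrame(session.y.T, columns=session.channel_names)
    df[_TRIGGER_COL] = session.x
    df.to_csv(path, index=False)
    Path(str(path) + ".meta").write_text(f"fs={session.fs}\n")


def _read_csv(path: Path) -> SessionData:
    meta = Path(str(path) + ".meta")
    if not meta.exists():
        raise ValueError(f"missing sampling-rate sidecar {meta}")
    kv = {}
    for line in meta.read_text().splitlines():
        line = line.strip()
        if line and "=" in line:
            k, v = line.split("=", 1)
            kv[k.strip()] = v.strip()
    if "fs" not in kv:
        raise ValueError(f"sidecar {meta} lacks an 'fs' entry")
    df = pd.read_csv(path)
    if _TRIGGER_COL not in df.columns:
        raise ValueError(f"CSV session must contain a '{_TRIGGER_COL}' column")
    chans = [c for c in df.columns if c != _TRIGGER_COL]
    return SessionData(
        y=df[chans].to_numpy().T,
        x=df[_TRIGGER_COL].to_numpy(),
        fs=float(kv["fs"]),
        channel_names=chans,
    )


def _read_edf(path: Path, trigger_channel: str) -> SessionData:
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF support requires the optional 'pyedflib' package"
        ) from exc
    with pyedflib.EdfReader(str(path)) as f:  # pragma: no cover
        labels = f.getSignalLabels()
        if trigger_channel not in labels:
            raise ValueError(
                f"trigger channel {trigger_channel!r} not found; "
                f"available channels: {labels}"
            )
        trig_idx = labels.index(trigger_channel)
        chan_idx = [i for i in range(len(labels)) if i != trig_idx]
        fs = f.getSampleFrequency(chan_idx[0])
        y = np.vstack([f.readSignal(i) for i in chan_idx])
        x = f.readSignal(trig_idx)
        return SessionData(y=y, x=x, fs=float(fs),
                           channel_names=[labels[i] for i in chan_idx])
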