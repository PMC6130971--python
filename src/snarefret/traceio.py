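"""Reading and writing two-channel intensity traces.

Two interchange formats are supported:

* long-form CSV/TSV with columns ``molecule_id, field_id, frame, donor,
  acceptor`` (comma delimiter, '.' decimal point, UTF-8, header row) —
  the canonical text format;
* HDF5 with layout ``/fields/<field_id>/<molecule_id>`` holding one
  ``(2, T)`` dataset (row 0 donor, row 1 acceptor) — the bulk format.

Frames are 0-based and must be contiguous per molecule; the time of a
frame is ``frame / frame_rate`` (frame start).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["molecule_id", "field_id", "frame", "donor", "acceptor"]


class TraceFormatError(ValueError):
    """Malformed trace file: wrong columns or unknown format."""


class TraceIntegrityError(ValueError):
    """Well-formed file with inconsistent content (ragged channels,
    non-contiguous frames, mixed frame rates)."""


@dataclass
class IntensityTrace:
    """Raw per-frame donor/acceptor intensities of one molecule."""

    molecule_id: str
    field_id: str
    frame_rate: float
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise TraceIntegrityError(
                f"{self.molecule_id}: donor/acceptor must be 1-D and equal length"
            )
        if self.donor.size < 1:
            raise TraceIntegrityError(f"{self.molecule_id}: empty trace")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.donor.size)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityTrace):
            return NotImplemented
        return (
            self.molecule_id == other.molecule_id
            and self.field_id == other.field_id
            and np.isclose(self.frame_rate, other.frame_rate)
            and np.allclose(self.donor, other.donor)
            and np.allclose(self.acceptor, other.acceptor)
        )


@dataclass
class TraceSet:
    """A collection of traces sharing one acquisition (one frame rate)."""

    traces: list[IntensityTrace] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = {t.frame_rate for t in self.traces}
        if len(rates) > 1:
            raise TraceIntegrityError(f"mixed frame rates in TraceSet: {sorted(rates)}")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    @property
    def frame_rate(self) -> float | None:
        return self.traces[0].frame_rate if self.traces else self.metadata.get("frame_rate")

    def by_field(self) -> dict[str, list[IntensityTrace]]:
        out: dict[str, list[IntensityTrace]] = {}
        for t in self.traces:
            out.setdefault(t.field_id, []).append(t)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TraceSet):
            return NotImplemented
        if len(self) != len(other):
            return False
        key = lambda t: (t.field_id, t.molecule_id)
        return all(a == b for a, b in zip(sorted(self.traces, key=key),
                                          sorted(other.traces, key=key)))


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in {".csv", ".tsv"}:
        return "csv" if suffix == ".csv" else "tsv"
    if suffix in {".h5", ".hdf5"}:
        return "hdf5"
    raise TraceFormatError(f"cannot infer trace format from suffix {suffix!r}")


def read_traces(path: str | Path, fmt: str | None = None,
                frame_rate: float | None = None) -> TraceSet:
    """Load a :class:`TraceSet` from CSV/TSV or HDF5.

    For text formats ``frame_rate`` must be supplied (text files carry no
    metadata header) unless the default of 10 Hz is acceptable.  Raises
    :class:`TraceFormatError` for missing columns and
    :class:`TraceIntegrityError` for non-contiguous frames or ragged
    channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt in {"csv", "tsv"}:
        return _read_text(path, sep="," if fmt == "csv" else "\t",
                          frame_rate=10.0 if frame_rate is None else frame_rate)
    if fmt == "hdf5":
        return _read_hdf5(path)
    raise TraceFormatError(f"unknown format {fmt!r}")


def _read_text(path: Path, sep: str, frame_rate: float) -> TraceSet:
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty trace file, returning empty TraceSet")
        return TraceSet([], metadata={"frame_rate": frame_rate})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: no rows in trace file, returning empty TraceSet")
        return TraceSet([], metadata={"frame_rate": frame_rate})
    traces = []
    for (fid, mid), grp in df.groupby(["field_id", "molecule_id"], sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise TraceIntegrityError(
                f"molecule {mid}: frames must be contiguous 0-based integers"
            )
        traces.append(IntensityTrace(str(mid), str(fid), frame_rate,
                                     grp["donor"].to_numpy(),
                                     grp["acceptor"].to_numpy()))
    return TraceSet(traces, metadata={"frame_rate": frame_rate})


def _read_hdf5(path: Path) -> TraceSet:
    traces = []
    with h5py.File(path, "r") as f:
        metadata = dict(f.attrs)
        fields = f.get("fields")
        if fields is None:
            warnings.warn(f"{path}: no /fields group, returning empty TraceSet")
            return TraceSet([], metadata=metadata)
        for fid in sorted(fields):
            for mid in sorted(fields[fid]):
                ds = fields[fid][mid]
                arr = np.asarray(ds)
                if arr.ndim != 2 or arr.shape[0] != 2:
                    raise TraceIntegrityError(
                        f"dataset /fields/{fid}/{mid} must have shape (2, T)"
                    )
                traces.append(IntensityTrace(
                    str(mid), str(fid), float(ds.attrs["frame_rate"]),
                    arr[0], arr[1]))
    return TraceSet(traces, metadata=metadata)


def write_traces(ts: TraceSet, path: str | Path, fmt: str | None = None,
                 overwrite: bool = False) -> None:
    """Write a :class:`TraceSet`; refuses to clobber unless ``overwrite``."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    if fmt in {"csv", "tsv"}:
        _write_text(ts, path, sep="," if fmt == "csv" else "\t")
    elif fmt == "hdf5":
        _write_hdf5(ts, path)
    else:
        raise TraceFormatError(f"unknown format {fmt!r}")


def _write_text(ts: TraceSet, path: Path, sep: str) -> None:
    chunks = []
    for t in ts:
        chunks.append(pd.DataFrame({
            "molecule_id": t.molecule_id,
            "field_id": t.field_id,
            "frame": np.arange(t.n_frames),
            "donor": t.donor,
            "acceptor": t.acceptor,
        }))
    df = (pd.concat(chunks, ignore_index=True) if chunks
          else pd.DataFrame(columns=CSV_COLUMNS))
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def _write_hdf5(ts: TraceSet, path: Path) -> None:
    with h5py.File(path, "w") as f:
        for k, v in ts.metadata.items():
            try:
                f.attrs[k] = v
            except TypeError:
                f.attrs[k] = str(v)
        fields = f.create_group("fields")
        for t in ts:
            grp = fields.require_group(t.field_id)
            ds = grp.create_dataset(t.molecule_id,
                                    data=np.vstack([t.donor, t.acceptor]))
            ds.attrs["frame_rate"] = t.frame_rate
            if "condition" in ts.metadata:
                ds.attrs["condition"] = ts.metadata["condition"]


def write_table(df: pd.DataFrame, path: str | Path, header_comment: str | None = None,
                overwrite: bool = True) -> None:
    """Write a results table as CSV with an optional ``#`` provenance header."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(path)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.10g")
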