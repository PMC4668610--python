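"""Reading and writing labeled multichannel EMG recordings.

Supported containers:

* **HDF5** (``.h5``/``.hdf5``): datasets ``/signal`` (channels x samples),
  ``/labels``, ``/trial_ids``; root attributes ``fs``, ``n_rows``,
  ``n_cols``, ``ied_mm``.  Lossless round-trip format.
* **Delimited matrix** (``.csv``/``.tsv``/``.txt``): channels x samples,
  with a JSON sidecar ``<path>.json`` carrying ``fs``, ``n_rows``,
  ``n_cols``, ``ied_mm``, ``labels`` and ``trial_ids``.
* **EDF** (``.edf``): read-only, via :mod:`mne` when it is installed; labels
  must come from a JSON sidecar (EDF carries no per-sample label track).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .exceptions import FormatError, InvalidArgumentError
from .grid import ElectrodeGrid, ShiftScheme, build_grid

__all__ = [
    "LabeledRecording",
    "read_recording",
    "write_recording",
    "write_partition_csv",
]


@dataclass
class LabeledRecording:
    """Multichannel EMG signal with per-sample motion labels and trial ids.

    Attributes
    ----------
    signal : ndarray, shape (channels, samples)
        Monopolar amplitudes, arbitrary units.
    fs : float
        Sampling rate in samples/second.
    labels : ndarray of int, shape (samples,)
        Motion identifier per sample (``0..n_motions-1``).
    trial_ids : ndarray of int, shape (samples,)
        Trial index per sample; trials are contiguous runs.
    grid : ElectrodeGrid
        Electrode layout; its size must equal the channel count.
    """

    signal: np.ndarray
    fs: float
    labels: np.ndarray
    trial_ids: np.ndarray
    grid: ElectrodeGrid = field(repr=False)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64).ravel()
        self.trial_ids = np.asarray(self.trial_ids, dtype=np.int64).ravel()
        if self.signal.ndim != 2:
            raise InvalidArgumentError("signal must be 2-D (channels x samples)")
        c, n = self.signal.shape
        if c != self.grid.n_channels:
            raise FormatError(
                f"signal has {c} channels but grid declares {self.grid.n_channels}"
            )
        if not self.fs > 0:
            raise InvalidArgumentError(f"fs must be > 0, got {self.fs}")
        if self.labels.shape != (n,) or self.trial_ids.shape != (n,):
            raise FormatError(
                "labels and trial_ids must align with the sample axis "
                f"(expected length {n})"
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def trial_slices(self) -> list[tuple[int, slice]]:
        """Contiguous ``(trial_id, sample_slice)`` runs in temporal order."""
        ids = self.trial_ids
        if ids.size == 0:
            return []
        boundaries = np.flatnonzero(np.diff(ids)) + 1
        starts = np.concatenate([[0], boundaries])
        stops = np.concatenate([boundaries, [ids.size]])
        return [(int(ids[a]), slice(int(a), int(b))) for a, b in zip(starts, stops)]


# ---------------------------------------------------------------------------
# writers


def write_recording(path: "str | Path", recording: LabeledRecording) -> Path:
    """Write a recording; the container is chosen from the file extension."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in (".h5", ".hdf5"):
        _write_hdf5(path, recording)
    elif ext in (".csv", ".tsv", ".txt"):
        _write_delimited(path, recording)
    else:
        raise FormatError(f"unsupported output format {ext!r}")
    return path


def _write_hdf5(path: Path, rec: LabeledRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("labels", data=rec.labels)
        f.create_dataset("trial_ids", data=rec.trial_ids)
        f.attrs["fs"] = rec.fs
        f.attrs["n_rows"] = rec.grid.n_rows
        f.attrs["n_cols"] = rec.grid.n_cols
        f.attrs["ied_mm"] = rec.grid.ied_mm


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_delimited(path: Path, rec: LabeledRecording) -> None:
    delim = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    np.savetxt(path, rec.signal, delimiter=delim, fmt="%.17g")
    sidecar = {
        "fs": rec.fs,
        "n_rows": rec.grid.n_rows,
        "n_cols": rec.grid.n_cols,
        "ied_mm": rec.grid.ied_mm,
        "labels": rec.labels.tolist(),
        "trial_ids": rec.trial_ids.tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))


def write_partition_csv(path: "str | Path", scheme: ShiftScheme) -> Path:
    """Export a shift scheme's partitions as (scheme, channel, row, col, role)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["scheme", "channel", "row", "col", "role"])
        for role, chans in (("train", scheme.train_channels),
                            ("test", scheme.test_channels)):
            for ch in chans:
                row, col = scheme.grid.row_col(ch)
                writer.writerow([scheme.name, ch, row, col, role])
    return path


# ---------------------------------------------------------------------------
# readers


def read_recording(path: "str | Path") -> LabeledRecording:
    """Read a recording written by :func:`write_recording` (or an EDF file).

    Raises
    ------
    FormatError
        On channel-count mismatch with the declared grid or missing sidecar
        fields.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    ext = path.suffix.lower()
    if ext in (".h5", ".hdf5"):
        return _read_hdf5(path)
    if ext in (".csv", ".tsv", ".txt"):
        return _read_delimited(path)
    if ext == ".edf":
        return _read_edf(path)
    raise FormatError(f"unsupported input format {ext!r}")


def _read_hdf5(path: Path) -> LabeledRecording:
    with h5py.File(path, "r") as f:
        for key in ("signal", "labels", "trial_ids"):
            if key not in f:
                raise FormatError(f"HDF5 file missing dataset /{key}")
        for attr in ("fs", "n_rows", "n_cols", "ied_mm"):
            if attr not in f.attrs:
                raise FormatError(f"HDF5 file missing attribute {attr}")
        grid = build_grid(int(f.attrs["n_rows"]), int(f.attrs["n_cols"]),
                          float(f.attrs["ied_mm"]))
        return LabeledRecording(
            signal=f["signal"][()],
            fs=float(f.attrs["fs"]),
            labels=f["labels"][()],
            trial_ids=f["trial_ids"][()],
            grid=grid,
        )


def _load_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    missing = [k for k in ("fs", "n_rows", "n_cols", "ied_mm", "labels",
                           "trial_ids") if k not in meta]
    if missing:
        raise FormatError(f"sidecar {sidecar} missing fields: {missing}")
    return meta


def _read_delimited(path: Path) -> LabeledRecording:
    meta = _load_sidecar(path)
    delim = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    signal = np.loadtxt(path, delimiter=delim, ndmin=2)
    grid = build_grid(int(meta["n_rows"]), int(meta["n_cols"]),
                      float(meta["ied_mm"]))
    return LabeledRecording(
        signal=signal,
        fs=float(meta["fs"]),
        labels=np.asarray(meta["labels"]),
        trial_ids=np.asarray(meta["trial_ids"]),
        grid=grid,
    )


def _read_edf(path: Path) -> LabeledRecording:
    try:
        import mne  # noqa: PLC0415 — optional dependency
    except ImportError as exc:  # pragma: no cover
        raise FormatError(
            "reading EDF requires the optional 'mne' package"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    meta = _load_sidecar(path)
    grid = build_grid(int(meta["n_rows"]), int(meta["n_cols"]),
                      float(meta["ied_mm"]))
    return LabeledRecording(
        signal=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        labels=np.asarray(meta["labels"]),
        trial_ids=np.asarray(meta["trial_ids"]),
        grid=grid,
    )
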