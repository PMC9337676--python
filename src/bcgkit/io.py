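"""Reading and writing recordings and annotation tracks.

The primary on-disk format is human-inspectable delimited text:

* recording: one sample per row, one tab-separated column per channel, with a
  JSON metadata sidecar ``<path>.meta.json`` holding the sampling rate,
  channel names and start time;
* annotations: a two-column TSV (``time_s``, ``label``) with the source
  recorded in a comment line.

Round trips are lossless to full ``repr`` precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, InputError

__all__ = [
    "Recording",
    "AnnotationTrack",
    "write_recording",
    "read_recording",
    "write_annotations",
    "read_annotations",
]

_SIDECAR_SUFFIX = ".meta.json"


@dataclass
class Recording:
    """Uniformly sampled multi-channel signal in millivolts.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, n_samples)``.
    fs:
        Sampling rate in Hz; must be positive.
    channel_names:
        One name per channel; defaults to ``ch0 .. chN``.
    start_time:
        Offset of sample 0 in seconds from recording start (default 0).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise InputError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass
class AnnotationTrack:
    """Ordered event times (seconds) with a label and a provenance tag."""

    event_times: np.ndarray
    label: str = "R"
    source: str = "unknown"

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float).ravel()
        if self.event_times.size > 1 and np.any(np.diff(self.event_times) <= 0):
            raise InputError("event times must be strictly ascending")

    def __len__(self) -> int:
        return self.event_times.size


def write_recording(rec: Recording, path: str | Path) -> tuple[Path, Path]:
    """Write ``rec`` as sample-per-row TSV plus a JSON sidecar.

    Returns the ``(data_path, sidecar_path)`` pair.
    """
    path = Path(path)
    sidecar = Path(str(path) + _SIDECAR_SUFFIX)
    header = "\t".join(rec.channel_names)
    rows = "\n".join(
        "\t".join(repr(float(v)) for v in rec.data[:, i]) for i in range(rec.n_samples)
    )
    path.write_text(header + "\n" + rows + ("\n" if rec.n_samples else ""))
    sidecar.write_text(
        json.dumps(
            {
                "fs": rec.fs,
                "channel_names": rec.channel_names,
                "start_time": rec.start_time,
                "n_channels": rec.n_channels,
                "n_samples": rec.n_samples,
            },
            indent=2,
        )
    )
    return path, sidecar


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    sidecar = Path(str(path) + _SIDECAR_SUFFIX)
    if not sidecar.exists():
        raise FormatError(f"missing metadata sidecar {sidecar}")
    if not path.exists():
        raise FormatError(f"missing data file {path}")
    meta = json.loads(sidecar.read_text())
    fs = float(meta.get("fs", 0))
    if fs <= 0:
        raise FormatError(f"fs must be positive in sidecar, got {fs}")
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"empty data file {path}")
    names = lines[0].split("\t")
    n_ch = len(names)
    samples = []
    for row_no, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != n_ch:
            raise FormatError(
                f"ragged data: row {row_no} has {len(cols)} columns, expected {n_ch}"
            )
        samples.append([float(c) for c in cols])
    data = (
        np.array(samples, dtype=float).T
        if samples
        else np.empty((n_ch, 0), dtype=float)
    )
    return Recording(
        data=data,
        fs=fs,
        channel_names=list(meta.get("channel_names", names)),
        start_time=float(meta.get("start_time", 0.0)),
    )


def write_annotations(track: AnnotationTrack, path: str | Path) -> Path:
    """Write an annotation track as a two-column TSV."""
    path = Path(path)
    lines = [f"# source: {track.source}", "time_s\tlabel"]
    lines += [f"{float(t)!r}\t{track.label}" for t in track.event_times]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read a track written by :func:`write_annotations`; rejects non-ascending times."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"missing annotation file {path}")
    source = "unknown"
    times: list[float] = []
    label = "R"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "source:" in line:
                source = line.split("source:", 1)[1].strip()
            continue
        if line.startswith("time_s"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise FormatError(f"expected two columns, got {line!r}")
        times.append(float(cols[0]))
        label = cols[1]
    arr = np.asarray(times)
    if arr.size > 1 and np.any(np.diff(arr) <= 0):
        raise FormatError("annotation times are not strictly ascending")
    return AnnotationTrack(event_times=arr, label=label, source=source)
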