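"""Windowed segmentation, amplitude QC and zero-phase band-pass filtering.

Recordings are split into overlapping fixed-length windows; each window's raw
peak-to-peak amplitude classifies it as usable, heavy-noise (saturation) or
no-contact (flat line), and only usable windows feed downstream analysis.
Band-pass filtering removes respiration and high-frequency noise without
shifting peak timing (forward-backward Butterworth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .errors import InputError, ParameterError
from .io import Recording

__all__ = [
    "Segment",
    "QCThresholds",
    "segment_signal",
    "amplitude_qc",
    "apply_qc",
    "bandpass",
    "qc_report",
]

QC_OK = "ok"
QC_HEAVY_NOISE = "heavy_noise"
QC_NO_CONTACT = "no_contact"


@dataclass
class QCThresholds:
    """Amplitude QC band in mV: >= high is heavy noise, <= low is no contact."""

    high: float = 85.0
    low: float = 35.0

    def validate(self) -> None:
        if not (self.high > self.low > 0):
            raise ParameterError(
                f"need high > low > 0, got high={self.high} low={self.low}"
            )


@dataclass
class Segment:
    channel: int
    start_sample: int
    length: int
    qc_status: str = QC_OK
    peak_to_peak: float = 0.0

    @property
    def stop_sample(self) -> int:
        return self.start_sample + self.length


def segment_signal(
    rec: Recording, window_s: float = 1.0, overlap: float = 0.5
) -> list[Segment]:
    """Split every channel into windows of ``window_s`` with fractional overlap.

    Window length W = round(window_s * fs), hop H = round(W * (1 - overlap));
    starts are 0, H, 2H, ... while the full window fits; trailing partial
    windows are discarded.
    """
    if not (0 <= overlap < 1):
        raise ParameterError(f"overlap must be in [0, 1), got {overlap}")
    w = int(round(window_s * rec.fs))
    if w < 2:
        raise ParameterError(f"window of {window_s}s at fs={rec.fs} is too short")
    hop = int(round(w * (1 - overlap)))
    if hop < 1:
        raise ParameterError("overlap too large: hop rounds to zero samples")
    segments = []
    n = rec.n_samples
    for ch in range(rec.n_channels):
        start = 0
        while start + w <= n:
            segments.append(Segment(channel=ch, start_sample=start, length=w))
            start += hop
    return segments


def amplitude_qc(samples: np.ndarray, thresholds: QCThresholds | None = None) -> str:
    """Classify a segment by raw peak-to-peak amplitude.

    ``>= high`` -> heavy noise, ``<= low`` -> no contact, otherwise ok.
    """
    thresholds = thresholds or QCThresholds()
    thresholds.validate()
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise InputError("cannot QC an empty segment")
    p2p = float(np.ptp(samples))
    if p2p >= thresholds.high:
        return QC_HEAVY_NOISE
    if p2p <= thresholds.low:
        return QC_NO_CONTACT
    return QC_OK


def apply_qc(
    rec: Recording,
    segments: list[Segment],
    thresholds: QCThresholds | None = None,
) -> list[Segment]:
    """Fill in ``peak_to_peak`` and ``qc_status`` for each segment in place.

    QC uses the raw (unfiltered) signal.
    """
    thresholds = thresholds or QCThresholds()
    for seg in segments:
        samples = rec.data[seg.channel, seg.start_sample : seg.stop_sample]
        seg.peak_to_peak = float(np.ptp(samples))
        seg.qc_status = amplitude_qc(samples, thresholds)
    return segments


def qc_report(segments: list[Segment], n_channels: int) -> dict[int, dict[str, int]]:
    """Per-channel counts of each QC status."""
    report = {
        ch: {QC_OK: 0, QC_HEAVY_NOISE: 0, QC_NO_CONTACT: 0} for ch in range(n_channels)
    }
    for seg in segments:
        report[seg.channel][seg.qc_status] += 1
    return report


def bandpass(
    rec: Recording, low: float = 1.0, high: float = 9.0, order: int = 4
) -> Recording:
    """Zero-phase Butterworth band-pass, preserving shape and sampling rate."""
    if not (0 < low < high):
        raise ParameterError(f"need 0 < low < high, got {low}, {high}")
    if high >= rec.fs / 2:
        raise ParameterError(
            f"high edge {high} Hz must be below Nyquist {rec.fs / 2} Hz"
        )
    sos = butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = sosfiltfilt(sos, rec.data, axis=1)
    return Recording(
        data=filtered,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        start_time=rec.start_time,
    )
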