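"""RR-interval series, physiological quality flags, channel selection, HRV.

Intervals outside the [0.5, 1.1] s plausibility band (closed at both ends)
are flagged bad; of the four chair-leg channels the one with the fewest bad
intervals represents the subject.  Time-domain features use good intervals
only; frequency-domain features use the longest contiguous run of good
intervals, resampled to an even 4 Hz tachogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import periodogram

from .errors import InputError, InsufficientDataError, NoUsableChannelError
from .io import AnnotationTrack

__all__ = [
    "RRISeries",
    "RRIBounds",
    "HRVFeatures",
    "rri_from_peaks",
    "flag_rri",
    "select_channel",
    "hrv_features",
]

GOOD = "good"
BAD_SHORT = "bad_short"
BAD_LONG = "bad_long"

#: minimum good-interval count for frequency-domain features
MIN_FREQ_INTERVALS = 64
TACHOGRAM_FS = 4.0  # Hz


@dataclass
class RRIBounds:
    """Closed acceptance band for plausible RR intervals, seconds."""

    min_rri: float = 0.5
    max_rri: float = 1.1

    def validate(self) -> None:
        if not (0 < self.min_rri < self.max_rri):
            raise InputError(
                f"need 0 < min < max, got {self.min_rri}, {self.max_rri}"
            )


@dataclass
class RRISeries:
    """Successive inter-beat intervals with onset times and quality flags."""

    intervals: np.ndarray
    onset_times: np.ndarray
    quality: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        if self.intervals.size != self.onset_times.size:
            raise InputError("intervals and onset_times must have equal length")
        if np.any(self.intervals <= 0):
            raise InputError("intervals must be positive")
        if not self.quality:
            self.quality = [GOOD] * self.intervals.size
        if len(self.quality) != self.intervals.size:
            raise InputError("quality flags must align with intervals")

    def __len__(self) -> int:
        return self.intervals.size

    @property
    def n_bad(self) -> int:
        return sum(q != GOOD for q in self.quality)

    def good_mask(self) -> np.ndarray:
        return np.asarray([q == GOOD for q in self.quality])


@dataclass
class HRVFeatures:
    mean_hr: float  # bpm
    sdnn: float  # s
    rmssd: float  # s
    pnn50: float  # fraction
    lf_power: float | None = None
    hf_power: float | None = None
    lf_hf_ratio: float | None = None

    def as_dict(self) -> dict:
        return {
            "mean_hr": self.mean_hr,
            "sdnn": self.sdnn,
            "rmssd": self.rmssd,
            "pnn50": self.pnn50,
            "lf_power": self.lf_power,
            "hf_power": self.hf_power,
            "lf_hf_ratio": self.lf_hf_ratio,
        }


def rri_from_peaks(track: AnnotationTrack) -> RRISeries:
    """Successive differences of the event times; onset is the earlier event.

    Fewer than two events yields an empty series.
    """
    times = np.asarray(track.event_times, dtype=float)
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise InputError("event times are unsorted")
    if times.size < 2:
        return RRISeries(intervals=np.array([]), onset_times=np.array([]))
    return RRISeries(intervals=np.diff(times), onset_times=times[:-1])


def flag_rri(series: RRISeries, bounds: RRIBounds | None = None) -> RRISeries:
    """Set per-interval quality: below the band bad_short, above it bad_long.

    Values exactly on a bound count as good (closed interval).
    """
    bounds = bounds or RRIBounds()
    bounds.validate()
    quality = [
        BAD_SHORT if rri < bounds.min_rri else BAD_LONG if rri > bounds.max_rri else GOOD
        for rri in series.intervals
    ]
    return RRISeries(
        intervals=series.intervals.copy(),
        onset_times=series.onset_times.copy(),
        quality=quality,
    )


def select_channel(series_per_channel: list[RRISeries]) -> int:
    """Index of the channel with the fewest bad intervals; ties take the
    lowest index."""
    if all(len(s) == 0 for s in series_per_channel):
        raise NoUsableChannelError("no usable channel: all series are empty")
    bad_counts = [s.n_bad for s in series_per_channel]
    return int(np.argmin(bad_counts))


def _longest_good_run(series: RRISeries) -> tuple[int, int]:
    """Half-open [start, stop) index range of the longest run of good flags."""
    best = (0, 0)
    start = None
    for i, q in enumerate(list(series.quality) + [None]):
        if q == GOOD:
            if start is None:
                start = i
        else:
            if start is not None and i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    return best


def hrv_features(
    series: RRISeries,
    use_only_good: bool = True,
) -> HRVFeatures:
    """Time- and frequency-domain HRV features from a flagged interval series.

    mean HR = 60/mean(RRI); SDNN = sample standard deviation (ddof=1);
    RMSSD = root-mean-square of successive differences; pNN50 = fraction of
    successive differences exceeding 50 ms.  Successive differences are taken
    between intervals adjacent in the original series (both good when
    ``use_only_good``).  Spectral LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz)
    powers come from the periodogram of the cubic-interpolated 4 Hz tachogram
    over the longest contiguous good run, and need >= 64 good intervals.
    """
    mask = series.good_mask() if use_only_good else np.ones(len(series), dtype=bool)
    rri = series.intervals[mask]
    if rri.size < 3:
        raise InsufficientDataError(
            f"insufficient data: {rri.size} usable intervals, need >= 3"
        )
    mean_hr = 60.0 / float(np.mean(rri))
    sdnn = float(np.std(rri, ddof=1))
    # successive differences between adjacent usable intervals
    adj = mask[:-1] & mask[1:]
    diffs = np.diff(series.intervals)[adj]
    if diffs.size:
        rmssd = float(np.sqrt(np.mean(diffs**2)))
        pnn50 = float(np.mean(np.abs(diffs) > 0.05))
    else:
        rmssd = 0.0
        pnn50 = 0.0

    lf = hf = ratio = None
    start, stop = _longest_good_run(series) if use_only_good else (0, len(series))
    if stop - start >= MIN_FREQ_INTERVALS:
        seg_rri = series.intervals[start:stop]
        seg_t = series.onset_times[start:stop]
        interp = interp1d(seg_t, seg_rri, kind="cubic")
        grid = np.arange(seg_t[0], seg_t[-1], 1.0 / TACHOGRAM_FS)
        tach = interp(grid)
        tach = tach - tach.mean()
        freqs, psd = periodogram(tach, fs=TACHOGRAM_FS)
        lf_band = (freqs >= 0.04) & (freqs < 0.15)
        hf_band = (freqs >= 0.15) & (freqs < 0.4)
        lf = float(np.trapezoid(psd[lf_band], freqs[lf_band]))
        hf = float(np.trapezoid(psd[hf_band], freqs[hf_band]))
        ratio = lf / hf if hf > 0 else None
    return HRVFeatures(
        mean_hr=mean_hr, sdnn=sdnn, rmssd=rmssd, pnn50=pnn50,
        lf_power=lf, hf_power=hf, lf_hf_ratio=ratio,
    )
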