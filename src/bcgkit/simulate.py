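"""Physics-grounded synthetic chair-BCG + reference ECG generator.

A single heartbeat's recoil force is modeled from three delayed copies of a
systolic pressure pulse traveling down the aorta: the net head-foot force is

    F(t) = A_D * [P1(t) - P2(t)] - A_A * [P0(t) - P1(t)]

which with physiological delays produces the characteristic negative-positive-
negative (I, J, K) beat morphology.  Forces are read out through a strain-gage
Wheatstone bridge treated as a static sensitivity, then summed with
respiration, baseline drift, sensor noise and sparse motion bursts, with the
sitter's weight unevenly distributed over the four chair-leg sensors.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InputError, ParameterError
from .io import Recording

__all__ = [
    "CardiacParams",
    "AorticParams",
    "BridgeParams",
    "ChannelLayout",
    "PairedRecording",
    "generate_rr_intervals",
    "bridge_output",
    "pressure_waveforms",
    "beat_force_waveform",
    "synth_ecg",
    "synth_bcg",
    "simulate_paired",
    "simulate_cohort",
]

#: nominal strain-gage resistance (ohms) and bridge excitation (volts)
NOMINAL_RESISTANCE = 350.0
NOMINAL_EXCITATION = 5.0

#: default lag from the ECG R-peak to the BCG J-peak, seconds
DEFAULT_R_TO_J_LATENCY = 0.25


@dataclass
class CardiacParams:
    """Beat-to-beat interval process parameters.

    Gaussian interval variability with a superposed respiratory sinus
    arrhythmia (RSA) sinusoid; intervals are clipped to [0.4, 1.5] s.
    """

    mean_rr: float = 0.8
    rr_sd: float = 0.03
    rsa_amplitude: float = 0.02
    rsa_freq: float = 0.25
    duration: float = 60.0
    seed: int = 0

    def validate(self) -> None:
        if self.mean_rr <= 0:
            raise ParameterError(f"mean_rr must be > 0, got {self.mean_rr}")
        if self.rr_sd < 0:
            raise ParameterError(f"rr_sd must be >= 0, got {self.rr_sd}")
        if self.duration <= 0:
            raise ParameterError(f"duration must be > 0, got {self.duration}")


@dataclass
class AorticParams:
    """Aortic geometry and pressure-pulse propagation parameters.

    The three pressure sites share one stereotyped raised-cosine systolic
    pulse; downstream sites see it delayed and slightly attenuated.
    """

    area_ascending: float = 5.0  # cm^2
    area_descending: float = 3.0  # cm^2
    pulse_width: float = 0.30  # s, raised-cosine support
    propagation_delay_01: float = 0.02  # s, inlet -> arch boundary
    propagation_delay_12: float = 0.04  # s, arch boundary -> outlet
    attenuation_01: float = 0.95
    attenuation_12: float = 0.90

    def validate(self) -> None:
        if self.area_ascending <= 0 or self.area_descending <= 0:
            raise ParameterError("aortic areas must be > 0")
        if self.propagation_delay_01 < 0 or self.propagation_delay_12 < 0:
            raise ParameterError("propagation delays must be >= 0")
        if self.pulse_width <= 0:
            raise ParameterError("pulse_width must be > 0")


@dataclass
class BridgeParams:
    """Wheatstone bridge arm resistances (ohms) and excitation (volts)."""

    r1: float = NOMINAL_RESISTANCE
    r2: float = NOMINAL_RESISTANCE
    r3: float = NOMINAL_RESISTANCE
    r4: float = NOMINAL_RESISTANCE
    excitation: float = NOMINAL_EXCITATION

    def validate(self) -> None:
        for name in ("r1", "r2", "r3", "r4"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")


@dataclass
class ChannelLayout:
    """Per-sensor mass distribution and additive disturbance levels."""

    weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    noise_sd: float = 0.0  # mV
    motion_artifact_rate: float = 0.0  # events / minute
    respiration_amplitude: float = 0.0  # mV
    respiration_freq: float = 0.25  # Hz
    drift_amplitude: float = 0.0  # mV

    def validate(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size != 4 or np.any(w < 0):
            raise ParameterError("weights must be 4 nonnegative fractions")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ParameterError(f"weights must sum to 1, got {w.sum()!r}")
        for name in (
            "noise_sd",
            "motion_artifact_rate",
            "respiration_amplitude",
            "respiration_freq",
            "drift_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class PairedRecording:
    """A synthetic 4-channel BCG with its ground-truth single-lead ECG."""

    bcg: Recording
    ecg: Recording
    fs: float
    true_r_times: np.ndarray
    true_j_times: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.true_r_times = np.asarray(self.true_r_times, dtype=float)
        self.true_j_times = np.asarray(self.true_j_times, dtype=float)
        if self.true_r_times.size != self.true_j_times.size:
            raise InputError("R and J event counts differ")
        if np.any(self.true_j_times <= self.true_r_times):
            raise InputError("every J time must follow its R time")


def generate_rr_intervals(params: CardiacParams) -> np.ndarray:
    """Draw a beat-interval sequence whose cumulative sum fits in ``duration``.

    Each interval is ``mean_rr + rr_sd * N(0,1) + RSA(t)`` clipped to
    [0.4, 1.5] s, where RSA(t) is a sinusoid evaluated at the running beat
    time.  With ``rr_sd = rsa_amplitude = 0`` the output is constant.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    intervals: list[float] = []
    t = 0.0
    while True:
        rr = params.mean_rr
        if params.rr_sd > 0:
            rr += params.rr_sd * rng.standard_normal()
        if params.rsa_amplitude > 0:
            rr += params.rsa_amplitude * np.sin(2 * np.pi * params.rsa_freq * t)
        rr = float(np.clip(rr, 0.4, 1.5))
        if t + rr > params.duration:
            break
        intervals.append(rr)
        t += rr
    return np.asarray(intervals)


def bridge_output(bridge: BridgeParams) -> float:
    """Differential output (V) of the Wheatstone bridge.

    ``e = (R1*R3 - R2*R4) / ((R1 + R2) * (R3 + R4)) * E``.
    """
    bridge.validate()
    num = bridge.r1 * bridge.r3 - bridge.r2 * bridge.r4
    den = (bridge.r1 + bridge.r2) * (bridge.r3 + bridge.r4)
    return num / den * bridge.excitation


def bridge_sensitivity(bridge: BridgeParams) -> float:
    """Small-signal gain d(e)/d(R1) around the configured operating point, V/ohm.

    The simulator uses the bridge as a static force -> resistance -> voltage
    sensitivity rather than a dynamic circuit model.
    """
    bridge.validate()
    delta = 1e-6
    perturbed = BridgeParams(
        bridge.r1 + delta, bridge.r2, bridge.r3, bridge.r4, bridge.excitation
    )
    return (bridge_output(perturbed) - bridge_output(bridge)) / delta


def _raised_cosine(t: np.ndarray, width: float) -> np.ndarray:
    """Raised-cosine pulse supported on [0, width], unit peak."""
    out = np.zeros_like(t)
    inside = (t >= 0) & (t <= width)
    out[inside] = 0.5 * (1 - np.cos(2 * np.pi * t[inside] / width))
    return out


def pressure_waveforms(
    aortic: AorticParams, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the three site pressure templates P0, P1, P2 on a common grid."""
    aortic.validate()
    if fs <= 0:
        raise ParameterError(f"fs must be > 0, got {fs}")
    total = aortic.pulse_width + aortic.propagation_delay_01 + aortic.propagation_delay_12
    t = np.arange(0.0, total + 1.0 / fs, 1.0 / fs)
    p0 = _raised_cosine(t, aortic.pulse_width)
    p1 = aortic.attenuation_01 * _raised_cosine(
        t - aortic.propagation_delay_01, aortic.pulse_width
    )
    p2 = (
        aortic.attenuation_01
        * aortic.attenuation_12
        * _raised_cosine(
            t - aortic.propagation_delay_01 - aortic.propagation_delay_12,
            aortic.pulse_width,
        )
    )
    return p0, p1, p2


def beat_force_waveform(aortic: AorticParams, fs: float) -> np.ndarray:
    """Single-beat recoil force template (arbitrary units) on a uniform grid.

    ``F = A_D*(P1 - P2) - A_A*(P0 - P1)``.  With the default delayed templates
    the waveform shows, in order, the I trough, the dominant J peak and the K
    trough.  Identical site pressures give the zero waveform.
    """
    p0, p1, p2 = pressure_waveforms(aortic, fs)
    return aortic.area_descending * (p1 - p2) - aortic.area_ascending * (p0 - p1)


def synth_ecg(
    r_times: np.ndarray,
    fs: float,
    duration: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Recording, np.ndarray]:
    """Place a sharp QRS-like template at each R time.

    Returns the single-channel recording and the R-peak sample indices; the
    local maximum within +/-0.05 s of each R time is exactly its nearest
    sample.
    """
    if fs <= 0 or duration <= 0:
        raise ParameterError("fs and duration must be > 0")
    r_times = np.asarray(r_times, dtype=float).ravel()
    if r_times.size > 1 and np.any(np.diff(r_times) <= 0):
        raise InputError("r_times must be strictly ascending")
    if r_times.size and (r_times[0] < 0 or r_times[-1] > duration):
        raise InputError("r_times must lie within [0, duration]")
    n = int(round(duration * fs))
    x = np.zeros(n)
    # narrow QRS: dominant positive spike flanked by small Q and S dips
    half = int(round(0.02 * fs))
    tt = np.arange(-3 * half, 3 * half + 1) / fs
    template = np.exp(-((tt / 0.008) ** 2))
    template -= 0.15 * np.exp(-(((tt + 0.025) / 0.008) ** 2))
    template -= 0.25 * np.exp(-(((tt - 0.025) / 0.008) ** 2))
    r_samples = np.round(r_times * fs).astype(int)
    for s in r_samples:
        lo = s - 3 * half
        hi = s + 3 * half + 1
        tlo = max(0, -lo)
        thi = len(template) - max(0, hi - n)
        x[max(0, lo) : min(n, hi)] += template[tlo:thi]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x += noise_sd * rng.standard_normal(n)
    rec = Recording(data=x[None, :], fs=fs, channel_names=["ECG"])
    return rec, r_samples


def synth_bcg(
    rr_intervals: np.ndarray,
    beat_template: np.ndarray,
    layout: ChannelLayout,
    bridge: BridgeParams,
    fs: float,
    duration: float,
    seed: int = 0,
    amplitude_mv: float = 60.0,
) -> tuple[Recording, np.ndarray]:
    """Render a 4-channel chair-leg BCG from a beat-interval sequence.

    A beat is placed at t=0 and at every cumulative interval; each channel is
    ``weight * (beat train (*) template)`` plus respiration, drift, Gaussian
    noise and sparse 0.5-s motion bursts, scaled through the bridge
    sensitivity so that an equal-weight channel's clean peak-to-peak is
    ``amplitude_mv``.  Returns the recording and the true J-peak times.
    """
    layout.validate()
    bridge.validate()
    if fs <= 0 or duration <= 0:
        raise ParameterError("fs and duration must be > 0")
    rr_intervals = np.asarray(rr_intervals, dtype=float).ravel()
    if np.any(rr_intervals <= 0):
        raise InputError("rr intervals must be > 0")
    beat_template = np.asarray(beat_template, dtype=float).ravel()
    if beat_template.size == 0 or np.ptp(beat_template) == 0:
        raise InputError("beat template must be a non-flat waveform")

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    beat_times = np.concatenate([[0.0], np.cumsum(rr_intervals)])
    beat_times = beat_times[beat_times <= duration]

    j_offset = int(np.argmax(beat_template))
    # beat train: template J sample lands exactly on the beat's J time
    train = np.zeros(n)
    j_times = []
    for bt in beat_times:
        j_sample = int(round(bt * fs)) + j_offset
        lo = j_sample - j_offset
        hi = lo + beat_template.size
        if j_sample >= n:
            continue
        tlo = max(0, -lo)
        thi = beat_template.size - max(0, hi - n)
        train[max(0, lo) : min(n, hi)] += beat_template[tlo:thi]
        j_times.append(j_sample / fs)

    # static readout gain, normalized so the nominal bridge gives 1.0
    gain = bridge_sensitivity(bridge) / bridge_sensitivity(BridgeParams())
    cal = amplitude_mv / (0.25 * np.ptp(beat_template)) * gain

    data = np.zeros((4, n))
    for ch in range(4):
        w = layout.weights[ch]
        x = w * cal * train
        if layout.respiration_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x += (
                4 * w * layout.respiration_amplitude
                * np.sin(2 * np.pi * layout.respiration_freq * t + phase)
            )
        if layout.drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            x += 4 * w * layout.drift_amplitude * np.sin(2 * np.pi * 0.05 * t + phase)
        if layout.noise_sd > 0:
            x += layout.noise_sd * rng.standard_normal(n)
        if layout.motion_artifact_rate > 0:
            n_events = rng.poisson(layout.motion_artifact_rate * duration / 60.0)
            burst_len = int(round(0.5 * fs))
            for _ in range(n_events):
                s = rng.integers(0, max(1, n - burst_len))
                x[s : s + burst_len] += (
                    2.0 * amplitude_mv * rng.standard_normal(burst_len)
                )
        data[ch] = x

    rec = Recording(data=data, fs=fs, channel_names=[f"leg{i}" for i in range(4)])
    return rec, np.asarray(j_times)


def simulate_paired(
    cardiac: CardiacParams,
    layout: ChannelLayout | None = None,
    aortic: AorticParams | None = None,
    bridge: BridgeParams | None = None,
    fs: float = 200.0,
    r_to_j_latency: float = DEFAULT_R_TO_J_LATENCY,
    latency_jitter_sd: float = 0.0,
    amplitude_mv: float = 60.0,
) -> PairedRecording:
    """Generate one BCG+ECG pair with known R and J times.

    R times are the beat onsets; each J time lags its R by ``r_to_j_latency``
    plus optional per-beat Gaussian jitter.
    """
    layout = layout or ChannelLayout()
    aortic = aortic or AorticParams()
    bridge = bridge or BridgeParams()
    cardiac.validate()
    if r_to_j_latency <= 0:
        raise ParameterError("r_to_j_latency must be > 0")

    rr = generate_rr_intervals(cardiac)
    rng = np.random.default_rng(cardiac.seed + 1)
    r_times = np.concatenate([[0.0], np.cumsum(rr)])
    # snap beats to the sample grid so R-to-J latency is exact after rendering
    r_times = np.round(r_times * fs) / fs
    lat = np.full(r_times.size, r_to_j_latency)
    if latency_jitter_sd > 0:
        lat += latency_jitter_sd * rng.standard_normal(r_times.size)
        lat = np.clip(lat, 0.05, None)
    template = beat_force_waveform(aortic, fs)
    j_offset_s = int(np.argmax(template)) / fs

    # keep beats whose J peak fits strictly inside the recording and whose
    # template start (J time minus the template's internal J offset) is >= 0
    keep = (
        (r_times + lat + (template.size / fs - j_offset_s) < cardiac.duration)
        & (r_times + lat - j_offset_s >= 0)
    )
    r_times, lat = r_times[keep], lat[keep]
    j_target = r_times + lat

    # anchor the beat train so each template's J sample lands on its target
    template_starts = j_target - j_offset_s
    rr_for_bcg = np.diff(template_starts)
    start_shift = template_starts[0]
    bcg, j_times = synth_bcg(
        rr_for_bcg if rr_for_bcg.size else np.asarray([1.0]),
        template,
        layout,
        bridge,
        fs,
        cardiac.duration - start_shift,
        seed=cardiac.seed + 2,
        amplitude_mv=amplitude_mv,
    )
    if rr_for_bcg.size == 0:
        j_times = j_times[:1]
    # re-embed with the initial latency offset
    n = int(round(cardiac.duration * fs))
    shift = int(round(start_shift * fs))
    data = np.zeros((4, n))
    m = min(bcg.n_samples, n - shift)
    data[:, shift : shift + m] = bcg.data[:, :m]
    bcg = Recording(data=data, fs=fs, channel_names=bcg.channel_names)
    m = min(r_times.size, len(j_times))
    r_times = r_times[:m]
    # the rendered J sample is round(j_target * fs) by construction; report
    # the exact target so j - r equals the configured latency bit-exactly
    j_times = j_target[:m]

    ecg, _ = synth_ecg(r_times, fs, cardiac.duration, seed=cardiac.seed + 3)
    return PairedRecording(
        bcg=bcg,
        ecg=ecg,
        fs=fs,
        true_r_times=r_times,
        true_j_times=j_times,
        params={
            "cardiac": asdict(cardiac),
            "layout": asdict(layout),
            "aortic": asdict(aortic),
            "bridge": asdict(bridge),
            "r_to_j_latency": r_to_j_latency,
            "latency_jitter_sd": latency_jitter_sd,
            "amplitude_mv": amplitude_mv,
        },
    )


def simulate_cohort(
    n_subjects: int,
    duration: float = 120.0,
    seed: int = 0,
    mean_rr_range: tuple[float, float] = (0.7, 1.0),
    rr_sd_range: tuple[float, float] = (0.02, 0.05),
    clean: bool = True,
    noise_sd: float = 4.0,
    motion_artifact_rate: float = 2.0,
    respiration_amplitude: float = 5.0,
    fs: float = 200.0,
    latency_jitter_sd: float = 0.0,
) -> list[PairedRecording]:
    """Generate an independent cohort of paired recordings.

    Per-subject cardiac parameters are drawn uniformly within the stated
    ranges and the chair-leg weight distribution from a Dirichlet; ``clean``
    disables all additive disturbances.
    """
    if n_subjects < 1:
        raise ParameterError("n_subjects must be >= 1")
    for rng_name, (lo, hi) in (
        ("mean_rr_range", mean_rr_range),
        ("rr_sd_range", rr_sd_range),
    ):
        if hi < lo:
            raise ParameterError(f"{rng_name} is empty: {(lo, hi)}")
    rng = np.random.default_rng(seed)
    cohort = []
    for i in range(n_subjects):
        cardiac = CardiacParams(
            mean_rr=float(rng.uniform(*mean_rr_range)),
            rr_sd=float(rng.uniform(*rr_sd_range)),
            rsa_amplitude=float(rng.uniform(0.005, 0.02)),
            rsa_freq=float(rng.uniform(0.2, 0.3)),
            duration=duration,
            seed=int(rng.integers(0, 2**31)),
        )
        weights = rng.dirichlet(np.full(4, 20.0))
        layout = ChannelLayout(
            weights=tuple(float(w) for w in weights),
            noise_sd=0.0 if clean else noise_sd,
            motion_artifact_rate=0.0 if clean else motion_artifact_rate,
            respiration_amplitude=0.0 if clean else respiration_amplitude,
        )
        cohort.append(
            simulate_paired(
                cardiac,
                layout=layout,
                fs=fs,
                latency_jitter_sd=latency_jitter_sd,
            )
        )
    return cohort
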