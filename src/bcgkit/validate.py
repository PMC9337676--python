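"""Tolerance-based peak matching, detection metrics and cross-validation.

The recording is partitioned into fixed-length epochs.  Predicted and true
events are paired one-to-one (maximum-cardinality, minimum total time
distance, only pairs within the tolerance count).  Each epoch then contributes
exactly one of TP / FN / FP / TN:

* epoch contains truth, all of it matched            -> TP
* epoch contains truth, some of it unmatched         -> FN
* epoch contains no truth but an unmatched prediction -> FP
* epoch contains neither                              -> TN
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import PipelineConfig
from .errors import (
    InputError,
    NoComparableDataError,
    ParameterError,
    UndefinedMetricError,
)
from .hrv import RRIBounds, RRISeries, flag_rri, rri_from_peaks, select_channel
from .io import AnnotationTrack
from .peaks import (
    PeakModel,
    StoppingCriteria,
    baseline_peak_detect,
    make_training_windows,
    predict_r_peaks,
    train_peak_model,
)
from .preprocess import QCThresholds, apply_qc, bandpass, segment_signal
from .simulate import PairedRecording

__all__ = [
    "MatchResult",
    "CrossvalReport",
    "match_peaks",
    "accuracy",
    "recall",
    "hr_error_bpm",
    "loso_crossval",
    "compare_methods",
]

_BIG = 1e9


@dataclass
class MatchResult:
    tp: int
    tn: int
    fp: int
    fn: int
    tolerance: float
    n_epochs: int

    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class CrossvalReport:
    """Per-fold detection metrics plus aggregate mean and SD."""

    folds: list[dict] = field(default_factory=list)
    models: list = field(default_factory=list)  # populated with keep_models=True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.folds)

    def aggregate(self) -> dict:
        frame = self.to_frame()
        out = {}
        for col in ("accuracy", "recall", "mean_abs_hr_error"):
            out[f"{col}_mean"] = float(frame[col].mean())
            out[f"{col}_sd"] = float(frame[col].std(ddof=0))
        return out


def _match_events(
    truth: np.ndarray, pred: np.ndarray, tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one pairing maximizing matches within tolerance.

    Returns boolean masks (truth_matched, pred_matched).  Uses a
    min-cost assignment where out-of-tolerance pairs carry a prohibitive
    cost, which yields the maximum-cardinality matching with minimum total
    |dt| among those.
    """
    t_matched = np.zeros(truth.size, dtype=bool)
    p_matched = np.zeros(pred.size, dtype=bool)
    if truth.size == 0 or pred.size == 0:
        return t_matched, p_matched
    dist = np.abs(truth[:, None] - pred[None, :])
    cost = np.where(dist <= tolerance, dist, _BIG)
    rows, cols = linear_sum_assignment(cost)
    for r, c in zip(rows, cols):
        if dist[r, c] <= tolerance:
            t_matched[r] = True
            p_matched[c] = True
    return t_matched, p_matched


def match_peaks(
    predicted: AnnotationTrack,
    truth: AnnotationTrack,
    tolerance: float = 0.1,
    epoch_len: float = 1.0,
    span: float | None = None,
) -> MatchResult:
    """Epoch-level confusion counts for event detection.

    ``span`` is the recording duration; defaults to covering the last event.
    A prediction may match a truth event across an epoch boundary as long as
    it is within tolerance.
    """
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    if epoch_len <= 0:
        raise ParameterError("epoch_len must be > 0")
    t = np.asarray(truth.event_times, dtype=float)
    p = np.asarray(predicted.event_times, dtype=float)
    if span is None:
        last = max(t[-1] if t.size else 0.0, p[-1] if p.size else 0.0)
        span = last + epoch_len
    n_epochs = max(1, int(np.ceil(span / epoch_len - 1e-12)))

    t_matched, p_matched = _match_events(t, p, tolerance)
    t_epoch = np.clip((t / epoch_len).astype(int), 0, n_epochs - 1)
    p_epoch = np.clip((p / epoch_len).astype(int), 0, n_epochs - 1)

    counts = np.bincount(t_epoch, minlength=n_epochs) if t.size else np.zeros(n_epochs, int)
    if np.any(counts > 1):
        warnings.warn(
            "epoch contains more than one truth event; epoch-level accounting "
            "assumes at most one",
            stacklevel=2,
        )
    tp = tn = fp = fn = 0
    for e in range(n_epochs):
        truths_here = t_epoch == e
        if truths_here.any():
            if t_matched[truths_here].all():
                tp += 1
            else:
                fn += 1
        else:
            unmatched_pred_here = ((p_epoch == e) & ~p_matched).any() if p.size else False
            if unmatched_pred_here:
                fp += 1
            else:
                tn += 1
    return MatchResult(tp=tp, tn=tn, fp=fp, fn=fn, tolerance=tolerance, n_epochs=n_epochs)


def accuracy(m: MatchResult) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    denom = m.total()
    if denom == 0:
        raise UndefinedMetricError("undefined metric: no epochs")
    return (m.tp + m.tn) / denom


def recall(m: MatchResult) -> float:
    """TP / (TP + FN)."""
    denom = m.tp + m.fn
    if denom == 0:
        raise UndefinedMetricError("undefined metric: no truth epochs")
    return m.tp / denom


def hr_error_bpm(
    pred_rri: RRISeries,
    true_rri: RRISeries,
    window_s: float = 10.0,
) -> tuple[float, float]:
    """Windowed heart-rate error (predicted - true), mean and SD in bpm.

    Heart rate per window is 60 / mean(RRI with onset inside the window);
    windows lacking intervals from either source are skipped.
    """
    if len(pred_rri) == 0 or len(true_rri) == 0:
        raise NoComparableDataError("no comparable data: an interval series is empty")
    if window_s <= 0:
        raise ParameterError("window_s must be > 0")
    start = max(pred_rri.onset_times[0], true_rri.onset_times[0])
    end = min(pred_rri.onset_times[-1], true_rri.onset_times[-1])
    errors = []
    w = start
    while w <= end:
        hrs = []
        for series in (pred_rri, true_rri):
            sel = (series.onset_times >= w) & (series.onset_times < w + window_s)
            if not sel.any():
                hrs = []
                break
            hrs.append(60.0 / float(np.mean(series.intervals[sel])))
        if hrs:
            errors.append(hrs[0] - hrs[1])
        w += window_s
    if not errors:
        raise NoComparableDataError("no comparable data: no overlapping windows")
    arr = np.asarray(errors)
    return float(arr.mean()), float(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# subject-level pipeline helpers shared by LOSO and method comparison
# ---------------------------------------------------------------------------


def _qc_exclusion_mask(pair: PairedRecording, config: PipelineConfig) -> np.ndarray:
    """Per-channel boolean mask of samples covered exclusively by bad segments."""
    rec = pair.bcg
    segments = segment_signal(rec, window_s=config.window_s, overlap=config.overlap)
    apply_qc(rec, segments, QCThresholds(high=config.qc_high, low=config.qc_low))
    covered = np.zeros((rec.n_channels, rec.n_samples), dtype=int)
    bad = np.zeros_like(covered)
    for seg in segments:
        covered[seg.channel, seg.start_sample : seg.stop_sample] += 1
        if seg.qc_status != "ok":
            bad[seg.channel, seg.start_sample : seg.stop_sample] += 1
    return (covered > 0) & (bad == covered)


def _prepare_subject(pair: PairedRecording, config: PipelineConfig):
    """Band-pass the BCG and compute the QC exclusion mask."""
    filtered = bandpass(
        pair.bcg, low=config.band_low, high=config.band_high, order=config.filter_order
    )
    return filtered, _qc_exclusion_mask(pair, config)


def _subject_windows(pair: PairedRecording, config: PipelineConfig):
    filtered, mask = _prepare_subject(pair, config)
    truth = AnnotationTrack(pair.true_r_times, label="R", source="simulated-truth")
    return make_training_windows(
        filtered,
        truth,
        window_s=config.model_window_s,
        min_spacing=config.min_spacing,
        prominence_factor=config.prominence_factor,
        exclude_mask=mask,
    )


def _train_on(
    cohort: list[PairedRecording],
    config: PipelineConfig,
    seed: int,
) -> PeakModel:
    windows = []
    for pair in cohort:
        windows.extend(_subject_windows(pair, config))
    if len(windows) > config.max_training_windows:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(windows), size=config.max_training_windows, replace=False)
        windows = [windows[i] for i in sorted(idx)]
    return train_peak_model(
        windows,
        criteria=StoppingCriteria(
            error_tol=config.error_tol,
            margin_tol=config.margin_tol,
            max_epochs=config.max_epochs,
        ),
        seed=seed,
        fs=config.fs,
        window_s=config.model_window_s,
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        momentum=config.momentum,
        clip_norm=config.clip_norm,
    )


def _detect_subject(
    pair: PairedRecording,
    config: PipelineConfig,
    model: PeakModel | None = None,
) -> tuple[list[AnnotationTrack], list[RRISeries], int]:
    """Run detection on all four channels and select the best one.

    With ``model`` None the conventional baseline picker is used.
    """
    filtered, mask = _prepare_subject(pair, config)
    bounds = RRIBounds(min_rri=config.min_rri, max_rri=config.max_rri)
    tracks, series = [], []
    for ch in range(filtered.n_channels):
        if model is not None:
            track = predict_r_peaks(
                model,
                filtered.data[ch],
                fs=filtered.fs,
                min_spacing=config.min_spacing,
                prominence_factor=config.prominence_factor,
                exclude_mask=mask[ch],
                offset_correction=config.offset_correction,
            )
        else:
            track = baseline_peak_detect(
                filtered.data[ch],
                fs=filtered.fs,
                min_spacing=config.min_spacing,
                window_s=config.baseline_window_s,
                k=config.baseline_k,
                time_offset=config.baseline_time_offset,
                exclude_mask=mask[ch],
            )
        tracks.append(track)
        series.append(flag_rri(rri_from_peaks(track), bounds))
    selected = select_channel(series)
    return tracks, series, selected


def _evaluate_subject(
    pair: PairedRecording,
    config: PipelineConfig,
    model: PeakModel | None,
) -> dict:
    tracks, series, selected = _detect_subject(pair, config, model)
    truth = AnnotationTrack(pair.true_r_times, label="R", source="simulated-truth")
    true_rri = rri_from_peaks(truth)
    m = match_peaks(
        tracks[selected],
        truth,
        tolerance=config.tolerance,
        epoch_len=config.epoch_len,
        span=pair.bcg.duration,
    )
    mean_err, sd_err = hr_error_bpm(series[selected], true_rri, window_s=config.hr_window_s)
    return {
        "selected_channel": selected,
        "tp": m.tp,
        "tn": m.tn,
        "fp": m.fp,
        "fn": m.fn,
        "accuracy": accuracy(m),
        "recall": recall(m),
        "mean_hr_error": mean_err,
        "sd_hr_error": sd_err,
        "mean_abs_hr_error": abs(mean_err),
    }


def loso_crossval(
    cohort: list[PairedRecording],
    config: PipelineConfig | None = None,
    seed: int = 0,
    keep_models: bool = False,
) -> CrossvalReport:
    """Leave-one-subject-out cross-validation of the CNN pipeline.

    For each subject a model is trained on all other subjects' windows and
    evaluated on the held-out subject's selected channel.  Deterministic for
    a fixed seed.
    """
    config = config or PipelineConfig()
    config.validate()
    if len(cohort) < 2:
        raise ParameterError("LOSO needs at least 2 subjects")
    report = CrossvalReport()
    for i, held_out in enumerate(cohort):
        train_set = [p for j, p in enumerate(cohort) if j != i]
        model = _train_on(train_set, config, seed=seed + i)
        row = _evaluate_subject(held_out, config, model)
        row["fold"] = i
        row["train_epochs"] = model.meta["epochs"]
        row["final_loss"] = model.meta["final_loss"]
        report.folds.append(row)
        if keep_models:
            report.models.append(model)
    return report


def compare_methods(
    cohort: list[PairedRecording],
    config: PipelineConfig | None = None,
    seed: int = 0,
    model: PeakModel | None = None,
) -> pd.DataFrame:
    """Per-subject metrics for the CNN pipeline vs the conventional baseline.

    A single model trained on the whole cohort is used unless one is given.
    """
    config = config or PipelineConfig()
    config.validate()
    if not cohort:
        raise InputError("empty cohort")
    if model is None:
        model = _train_on(cohort, config, seed=seed)
    rows = []
    for i, pair in enumerate(cohort):
        for method, mdl in (("cnn", model), ("baseline", None)):
            row = _evaluate_subject(pair, config, mdl)
            row["subject"] = i
            row["method"] = method
            rows.append(row)
    frame = pd.DataFrame(rows)
    return frame
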