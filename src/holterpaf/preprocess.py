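"""Preprocessing chain: ectopy excision, segmentation, gating, STFT.

The pipeline mirrors standard ambulatory-ECG practice for sinus-rhythm
analysis: a +/-3.5-s window around every annotated ventricular ectopic beat
is excised (removing the beat, couplets and T-wave turbulence); under
"setting 2" the same window is excised around supraventricular ectopy as
well, leaving pure sinus rhythm; the remaining signal is tiled into
non-overlapping 7-s, 3-channel segments (3 x 896 samples at 128 Hz), gated
for noise, Z-normalized per channel and transformed to log-magnitude STFT
spectrograms (Hann window of 50 samples, hop 25) before entering the CNN.

Segments are tagged DAY or NIGHT by their start clock time; nighttime is the
fixed interval [22:00, 07:00), half-open so the boundaries are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, time
from enum import Enum, IntEnum

import numpy as np

from .io import BeatAnnotation, BeatClass, HolterRecording, PatientRecord

__all__ = [
    "Setting",
    "Diurnal",
    "EcgSegment",
    "Spectrogram",
    "ExcisionMask",
    "SEGMENT_SECONDS",
    "SEGMENT_SAMPLES",
    "NOMINAL_FS",
    "EXCISION_HALF_WINDOW_S",
    "build_excision_mask",
    "extract_segments",
    "noise_gate",
    "znormalize",
    "stft_transform",
    "segments_to_spectrograms",
    "diurnal_tag",
    "label_segments",
    "preprocess_patient",
]

SEGMENT_SECONDS = 7.0
NOMINAL_FS = 128.0
#: samples per channel in one segment: 7 s x 128 Hz
SEGMENT_SAMPLES = int(SEGMENT_SECONDS * NOMINAL_FS)  # = 896
EXCISION_HALF_WINDOW_S = 3.5
STFT_WINDOW = 50
STFT_HOP = 25

NIGHT_START = time(22, 0, 0)
NIGHT_END = time(7, 0, 0)


class Setting(IntEnum):
    """Analysis settings: 1 keeps SVE segments, 2 excises SVE like VE."""

    WITH_SVE = 1
    WITHOUT_SVE = 2


class Diurnal(str, Enum):
    DAY = "DAY"
    NIGHT = "NIGHT"


@dataclass
class EcgSegment:
    """A 7-s, 3-channel ECG window with its metadata."""

    patient_id: str
    start_time: datetime
    samples: np.ndarray  # (3, 896)
    contains_sve: bool = False
    diurnal: Diurnal = Diurnal.DAY
    label: bool | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (3, SEGMENT_SAMPLES):
            raise ValueError(
                f"segment must be (3, {SEGMENT_SAMPLES}); got {self.samples.shape}"
            )


@dataclass
class Spectrogram:
    """Per-channel log-magnitude STFT of one segment."""

    values: np.ndarray  # (3, F, T), non-negative
    window_size: int
    hop: int

    def __post_init__(self) -> None:
        f_expect = self.window_size // 2 + 1
        t_expect = (SEGMENT_SAMPLES - self.window_size) // self.hop + 1
        if self.values.shape != (3, f_expect, t_expect):
            raise ValueError(
                f"spectrogram shape {self.values.shape} != (3, {f_expect}, {t_expect})"
            )


@dataclass
class ExcisionMask:
    """Sample intervals retained after event removal, plus a removal log."""

    n_samples: int
    kept_intervals: list[tuple[int, int]]
    removal_log: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = -1
        for a, b in self.kept_intervals:
            if not (0 <= a < b <= self.n_samples):
                raise ValueError(f"interval ({a}, {b}) outside [0, {self.n_samples})")
            if a <= prev_end:
                raise ValueError("kept intervals must be disjoint and sorted")
            prev_end = b

    @property
    def kept_samples(self) -> int:
        return sum(b - a for a, b in self.kept_intervals)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def build_excision_mask(
    recording: HolterRecording,
    annotations: list[BeatAnnotation],
    setting: Setting = Setting.WITH_SVE,
) -> ExcisionMask:
    """Remove +/-3.5 s around each ectopic beat; return what survives.

    Ventricular ectopy is excised under both settings (this also removes
    T-wave turbulence following the beat); supraventricular ectopy is excised
    only under setting 2.  Overlapping removal windows merge.
    """
    n = recording.n_samples
    half = int(round(EXCISION_HALF_WINDOW_S * recording.fs))
    removed: list[tuple[int, int]] = []
    log = {"VE_window": 0, "SVE_window": 0, "noise": 0}
    for ann in annotations:
        if ann.beat_class == BeatClass.VE:
            log["VE_window"] += 1
        elif ann.beat_class == BeatClass.SVE and setting == Setting.WITHOUT_SVE:
            log["SVE_window"] += 1
        else:
            continue
        removed.append((max(0, ann.sample_index - half),
                        min(n, ann.sample_index + half)))
    removed = _merge_intervals(removed)

    kept: list[tuple[int, int]] = []
    cursor = 0
    for a, b in removed:
        if a > cursor:
            kept.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < n:
        kept.append((cursor, n))
    return ExcisionMask(n_samples=n, kept_intervals=kept, removal_log=log)


def diurnal_tag(start_time: datetime | time) -> Diurnal:
    """NIGHT iff the clock time is in [22:00, 07:00), wrapping midnight."""
    t = start_time.time() if isinstance(start_time, datetime) else start_time
    if t >= NIGHT_START or t < NIGHT_END:
        return Diurnal.NIGHT
    return Diurnal.DAY


def extract_segments(
    recording: HolterRecording,
    mask: ExcisionMask,
    annotations: list[BeatAnnotation] | None = None,
) -> list[EcgSegment]:
    """Tile non-overlapping 7-s windows from the start of each kept interval.

    Windows shorter than 7 s at interval ends are discarded.  Each segment
    carries its start clock time, diurnal tag, and a ``contains_sve`` flag
    (true iff any SVE annotation falls inside the window).
    """
    seg_len = int(round(SEGMENT_SECONDS * recording.fs))
    sve_idx = np.array(
        [a.sample_index for a in (annotations or [])
         if a.beat_class == BeatClass.SVE],
        dtype=int,
    )
    segments: list[EcgSegment] = []
    for a, b in mask.kept_intervals:
        for s0 in range(a, b - seg_len + 1, seg_len):
            s1 = s0 + seg_len
            has_sve = bool(sve_idx.size and
                           np.any((sve_idx >= s0) & (sve_idx < s1)))
            t0 = recording.time_of_sample(s0)
            segments.append(
                EcgSegment(
                    patient_id=recording.patient_id,
                    start_time=t0,
                    samples=recording.signal[:, s0:s1],
                    contains_sve=has_sve,
                    diurnal=diurnal_tag(t0),
                )
            )
    return segments


def noise_gate(
    segment: EcgSegment,
    flat_variance: float = 1e-6,
    rail_mv: float = 5.0,
    max_clipped_fraction: float = 0.05,
    max_amplitude_mv: float = 10.0,
) -> bool:
    """Rule-based segment quality gate; returns True to keep.

    Drops a segment if any channel is flatline (variance below
    ``flat_variance`` mV^2), saturated (more than ``max_clipped_fraction`` of
    samples at or beyond ``rail_mv``), or outside the physiological amplitude
    range (any sample beyond ``max_amplitude_mv``).  Operates on raw,
    un-normalized samples.
    """
    if segment.normalized:
        raise ValueError("noise gate must see raw (un-normalized) samples")
    x = segment.samples
    if np.any(x.var(axis=1) < flat_variance):
        return False
    clipped = np.mean(np.abs(x) >= rail_mv, axis=1)
    if np.any(clipped > max_clipped_fraction):
        return False
    if np.any(np.abs(x) > max_amplitude_mv):
        return False
    return True


def znormalize(segment: EcgSegment) -> EcgSegment:
    """Per-channel (x - mean) / SD; zero-variance channels map to zeros."""
    x = segment.samples
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = np.where(sd > 1e-12, (x - mean) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return EcgSegment(
        patient_id=segment.patient_id,
        start_time=segment.start_time,
        samples=out,
        contains_sve=segment.contains_sve,
        diurnal=segment.diurnal,
        label=segment.label,
        normalized=True,
    )


def _hann(n: int) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(n) / n)


def stft_transform(
    segment: EcgSegment,
    window_size: int = STFT_WINDOW,
    hop: int = STFT_HOP,
) -> Spectrogram:
    """Per-channel log(1 + |STFT|) with a Hann window, no padding.

    Frame count T = floor((896 - window) / hop) + 1 and F = window//2 + 1
    frequency bins.
    """
    if window_size > SEGMENT_SAMPLES:
        raise ValueError("window_size exceeds segment length")
    x = segment.samples
    win = _hann(window_size)
    frames = np.lib.stride_tricks.sliding_window_view(
        x, window_size, axis=1)[:, ::hop, :]  # (3, T, W)
    spec = np.abs(np.fft.rfft(frames * win, axis=2))  # (3, T, F)
    values = np.log1p(spec).transpose(0, 2, 1)  # (3, F, T)
    return Spectrogram(values=values, window_size=window_size, hop=hop)


def segments_to_spectrograms(
    segments: list[EcgSegment],
    window_size: int = STFT_WINDOW,
    hop: int = STFT_HOP,
) -> np.ndarray:
    """Z-normalize (if needed) and STFT a batch; returns (n, 3, F, T)."""
    out = []
    for seg in segments:
        s = seg if seg.normalized else znormalize(seg)
        out.append(stft_transform(s, window_size, hop).values)
    return np.stack(out) if out else np.empty(
        (0, 3, window_size // 2 + 1,
         (SEGMENT_SAMPLES - window_size) // hop + 1))


def label_segments(
    segments: list[EcgSegment], patient: PatientRecord
) -> list[EcgSegment]:
    """Propagate the patient-level pAF label to every segment (in place)."""
    for seg in segments:
        seg.label = bool(patient.paf_label)
    return segments


def preprocess_patient(
    recording: HolterRecording,
    annotations: list[BeatAnnotation],
    patient: PatientRecord,
    setting: Setting = Setting.WITH_SVE,
    apply_noise_gate: bool = True,
) -> list[EcgSegment]:
    """Full per-patient chain: excise -> segment -> gate -> label.

    Returned segments are raw (un-normalized); normalization and STFT happen
    at spectrogram construction so the gate sees physical amplitudes.
    """
    mask = build_excision_mask(recording, annotations, setting)
    segments = extract_segments(recording, mask, annotations)
    if apply_noise_gate:
        segments = [s for s in segments if noise_gate(s)]
    return label_segments(segments, patient)
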