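"""Synthetic 3-channel Holter cohort simulator.

Generates labelled ambulatory ECG recordings with the statistical structure
the two-stage pipeline assumes, so every downstream stage is testable without
any clinical data:

* beats synthesised from parametric P/QRS/T pulse templates (Gaussian lobes
  for P and T, a raised-cosine lobe for the QRS) projected onto three
  channels (modified V5, modified V1, lead III);
* diurnal heart-rate modulation with a cosine-blended night plateau
  (nighttime fixed at 22:00-07:00);
* supraventricular and ventricular ectopy inserted as thinned Poisson
  processes at configured hourly rates, with premature coupling and a
  compensatory pause; every beat is annotated with its true class;
* the pAF "substrate" encoded as a P-wave morphology shift (fractional
  P-duration prolongation plus amplitude change) and an elevated SVE rate —
  the two information channels the CNN and the SVE-burden baseline can use;
* additive Gaussian noise; log-normal multiplicative RR jitter.

Effect sizes are configuration, not claims about real cohorts.  Setting
``p_wave_effect = 0`` and equal SVE rates defines the null cohort, for which
no classifier should beat chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .io import (
    BeatAnnotation,
    BeatClass,
    CohortManifest,
    HolterRecording,
    PatientRecord,
    write_cohort_manifest,
    write_record,
)

__all__ = [
    "SimConfig",
    "BeatTemplateParams",
    "diurnal_rate",
    "beat_template",
    "p_wave_duration",
    "generate_patient_recording",
    "generate_cohort",
]

#: average month length in days, used to convert elapsed months to dates
DAYS_PER_MONTH = 30.44


@dataclass
class BeatTemplateParams:
    """Morphology of a single beat; amplitudes are per channel (V5, V1, III)."""

    p_duration_ms: float = 100.0
    p_amplitude_mv: tuple[float, float, float] = (0.10, 0.14, 0.07)
    pr_interval_ms: float = 160.0
    qrs_duration_ms: float = 90.0
    qrs_amplitude_mv: tuple[float, float, float] = (1.1, 0.8, 0.6)
    st_interval_ms: float = 110.0
    t_duration_ms: float = 170.0
    t_amplitude_mv: tuple[float, float, float] = (0.30, 0.22, 0.15)
    include_p: bool = True

    def __post_init__(self) -> None:
        for name in ("p_duration_ms", "pr_interval_ms", "qrs_duration_ms",
                     "st_interval_ms", "t_duration_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pr_interval_ms < self.p_duration_ms:
            raise ValueError("P wave must fit inside the PR interval")


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Rates are events per hour; ``p_wave_effect`` is the fractional P-duration
    prolongation (and half-weighted amplitude increase) applied only to pAF
    patients.  ``p_wave_effect = 0`` with ``sve_rate_paf == sve_rate_control``
    defines the null cohort.
    """

    n_patients: int = 60
    paf_fraction: float = 0.3
    duration_s: float = 1200.0
    fs: float = 128.0
    mean_hr_day: float = 75.0
    mean_hr_night: float = 55.0
    p_wave_effect: float = 0.3
    sve_rate_control: float = 4.0
    sve_rate_paf: float = 7.0
    ve_rate: float = 2.0
    noise_sd: float = 0.05
    rr_jitter_sigma: float = 0.05
    hr_between_patient_sd: float = 3.0
    night_p_prolongation: float = 0.05
    start_clock: str = "09:00:00"
    exam_date: str = "2020-06-01"
    elapsed_months_low: float = 0.5
    elapsed_months_high: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.paf_fraction <= 1.0:
            raise ValueError("paf_fraction must be in [0, 1]")
        for name in ("sve_rate_control", "sve_rate_paf", "ve_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        if abs(self.duration_s * self.fs - round(self.duration_s * self.fs)) > 1e-9:
            raise ValueError("duration_s * fs must be an integer sample count")

    def null(self) -> "SimConfig":
        """The matched null cohort: no morphology shift, equal SVE rates."""
        return replace(
            self, p_wave_effect=0.0, sve_rate_paf=self.sve_rate_control
        )


# ---------------------------------------------------------------------------
# Diurnal heart-rate profile

_NIGHT_START_H = 22.0
_NIGHT_END_H = 7.0
_RAMP_H = 1.0  # width of each cosine transition


def _night_weight(hour: float) -> float:
    """Smooth 0..1 indicator of nighttime, cosine-blended over 1-h ramps."""
    h = hour % 24.0
    fall0, fall1 = _NIGHT_END_H - _RAMP_H / 2, _NIGHT_END_H + _RAMP_H / 2
    rise0, rise1 = _NIGHT_START_H - _RAMP_H / 2, _NIGHT_START_H + _RAMP_H / 2
    if h < fall0 or h >= rise1:
        return 1.0
    if fall1 <= h < rise0:
        return 0.0
    if fall0 <= h < fall1:  # 06:30-07:30, night -> day
        return 0.5 * (1.0 + math.cos(math.pi * (h - fall0) / _RAMP_H))
    # 21:30-22:30, day -> night
    return 0.5 * (1.0 - math.cos(math.pi * (h - rise0) / _RAMP_H))


def diurnal_rate(
    clock_time: datetime, mean_hr_day: float, mean_hr_night: float
) -> float:
    """Instantaneous heart rate (bpm) at a clock time.

    Day and night plateaus are blended with cosine ramps of one hour centred
    on the fixed 22:00 and 07:00 boundaries; the profile is 24-h periodic.
    """
    hour = (
        clock_time.hour + clock_time.minute / 60.0 + clock_time.second / 3600.0
        + clock_time.microsecond / 3.6e9
    )
    w = _night_weight(hour)
    return mean_hr_day + (mean_hr_night - mean_hr_day) * w


# ---------------------------------------------------------------------------
# Beat templates


def _gauss_lobe(n: int, center: float, duration: float, fs: float) -> np.ndarray:
    """Gaussian pulse truncated to +/- duration/2, unit peak."""
    t = np.arange(n) / fs
    sd = duration / 5.0
    lobe = np.exp(-0.5 * ((t - center) / sd) ** 2)
    lobe[np.abs(t - center) > duration / 2] = 0.0
    return lobe


def _raised_cosine_lobe(n: int, onset: float, duration: float, fs: float) -> np.ndarray:
    """Raised-cosine pulse on [onset, onset+duration], unit peak.

    Closed-form area of the continuous pulse is ``duration / 2``.
    """
    t = np.arange(n) / fs
    x = (t - onset) / duration
    lobe = np.where((x >= 0) & (x <= 1), 0.5 * (1 - np.cos(2 * np.pi * x)), 0.0)
    return lobe


def beat_template(params: BeatTemplateParams, fs: float) -> np.ndarray:
    """Render one beat as a ``(3, n)`` waveform in millivolts.

    Timeline: P onset at t=0; QRS onset at ``pr_interval``; T follows the QRS
    after ``st_interval``.  The R peak sits at ``pr + qrs/2`` (see
    :func:`r_peak_offset`).  With ``include_p=False`` the P deflection is
    absent (ectopic morphology).
    """
    p_dur = params.p_duration_ms / 1000.0
    pr = params.pr_interval_ms / 1000.0
    qrs = params.qrs_duration_ms / 1000.0
    st = params.st_interval_ms / 1000.0
    t_dur = params.t_duration_ms / 1000.0
    total = pr + qrs + st + t_dur + 0.04
    n = int(round(total * fs))

    out = np.zeros((3, n))
    if params.include_p:
        # P ends just before QRS onset (small isoelectric gap)
        p = _gauss_lobe(n, pr - p_dur / 2.0 - 0.01, p_dur, fs)
        for c in range(3):
            out[c] += params.p_amplitude_mv[c] * p
    q = _raised_cosine_lobe(n, pr, qrs, fs)
    t_on = pr + qrs + st
    tw = _gauss_lobe(n, t_on + t_dur / 2.0, t_dur, fs)
    for c in range(3):
        out[c] += params.qrs_amplitude_mv[c] * q
        out[c] += params.t_amplitude_mv[c] * tw
    return out


def r_peak_offset(params: BeatTemplateParams, fs: float) -> int:
    """Sample offset of the R peak inside :func:`beat_template` output."""
    return int(round((params.pr_interval_ms + params.qrs_duration_ms / 2.0)
                     / 1000.0 * fs))


def p_wave_duration(template: np.ndarray, fs: float, frac: float = 0.1) -> float:
    """Measure P duration (s) from a rendered template's V1 channel.

    Width of the contiguous region around the P peak exceeding ``frac`` of
    the peak amplitude, restricted to the pre-QRS window.  Used to read
    configured morphology effects back out of generated waveforms.
    """
    ch = template[1]
    # walk left from the R peak through the QRS to the isoelectric gap,
    # which bounds the pre-QRS (P-wave) region
    r = int(np.argmax(ch))
    q_on = r
    while q_on > 0 and ch[q_on - 1] > 1e-9:
        q_on -= 1
    pre = ch[:q_on]
    if pre.size == 0 or pre.max() <= 0:
        return 0.0
    peak = int(np.argmax(pre))
    thr = frac * pre[peak]
    lo = peak
    while lo > 0 and pre[lo - 1] > thr:
        lo -= 1
    hi = peak
    while hi < pre.size - 1 and pre[hi + 1] > thr:
        hi += 1
    return (hi - lo + 1) / fs


# ---------------------------------------------------------------------------
# Per-patient recording


def _paf_template_params(base: BeatTemplateParams, effect: float) -> BeatTemplateParams:
    """Apply the pAF P-wave morphology shift: duration x(1+e), amplitude x(1+e/2)."""
    return replace(
        base,
        p_duration_ms=base.p_duration_ms * (1.0 + effect),
        pr_interval_ms=max(base.pr_interval_ms,
                           base.p_duration_ms * (1.0 + effect) + 20.0),
        p_amplitude_mv=tuple(a * (1.0 + 0.5 * effect) for a in base.p_amplitude_mv),
    )


def _night_params(base: BeatTemplateParams, prolong: float) -> BeatTemplateParams:
    return replace(
        base,
        p_duration_ms=base.p_duration_ms * (1.0 + prolong),
        pr_interval_ms=max(base.pr_interval_ms,
                           base.p_duration_ms * (1.0 + prolong) + 20.0),
    )


_MIN_RR_S = 0.25  # beats closer than this to the previous are skipped


def generate_patient_recording(
    patient_id: str,
    config: SimConfig,
    rng: np.random.Generator,
    is_paf: bool,
    start_time: datetime | None = None,
) -> tuple[HolterRecording, list[BeatAnnotation]]:
    """Simulate one patient's recording and its ground-truth annotations.

    Beat times follow the diurnal rate with multiplicative log-normal RR
    jitter; SVE/VE arrivals are thinned Poisson processes at the configured
    hourly rates, inserted as premature beats (coupling ~0.65 RR) followed by
    a compensatory pause.  The signal is the sum of placed beat templates
    plus white Gaussian noise.  Beats whose RR to the previous beat falls
    below 0.25 s are skipped (counted, not placed).
    """
    fs = config.fs
    n = int(round(config.duration_s * fs))
    if start_time is None:
        clk = datetime.strptime(config.start_clock, "%H:%M:%S")
        start_time = datetime(2020, 6, 1, clk.hour, clk.minute, clk.second)

    base = BeatTemplateParams()
    normal_day = _paf_template_params(base, config.p_wave_effect) if is_paf else base
    normal_night = _night_params(normal_day, config.night_p_prolongation)
    sve_p = replace(normal_day, include_p=False)
    ve_p = replace(
        base,
        include_p=False,
        qrs_duration_ms=base.qrs_duration_ms * 1.9,
        qrs_amplitude_mv=tuple(1.4 * a for a in base.qrs_amplitude_mv),
        t_amplitude_mv=tuple(-a for a in base.t_amplitude_mv),
    )
    templates = {
        "day": beat_template(normal_day, fs),
        "night": beat_template(normal_night, fs),
        BeatClass.SVE: beat_template(sve_p, fs),
        BeatClass.VE: beat_template(ve_p, fs),
    }
    r_offsets = {
        "day": r_peak_offset(normal_day, fs),
        "night": r_peak_offset(normal_night, fs),
        BeatClass.SVE: r_peak_offset(sve_p, fs),
        BeatClass.VE: r_peak_offset(ve_p, fs),
    }

    hr_offset = rng.normal(0.0, config.hr_between_patient_sd)
    amp_scale = rng.uniform(0.9, 1.1)
    sve_rate = config.sve_rate_paf if is_paf else config.sve_rate_control
    ve_rate = config.ve_rate

    min_rr = _MIN_RR_S
    if config.duration_s * max(config.mean_hr_day, config.mean_hr_night) / 60.0 < 1:
        raise ValueError("duration too short to hold one beat")

    signal = np.zeros((3, n))
    annotations: list[BeatAnnotation] = []
    n_skipped = 0
    prev_t = -np.inf

    def place(t_beat: float, cls: BeatClass, night: bool) -> bool:
        nonlocal n_skipped, prev_t
        key = cls if cls in (BeatClass.SVE, BeatClass.VE) else (
            "night" if night else "day")
        tpl = templates[key]
        r_off = r_offsets[key]
        r_sample = int(round(t_beat * fs))
        s0 = r_sample - r_off
        s1 = s0 + tpl.shape[1]
        if s0 < 0 or s1 > n:
            return False
        if t_beat - prev_t < min_rr:
            n_skipped += 1
            return False
        signal[:, s0:s1] += amp_scale * tpl
        annotations.append(BeatAnnotation(sample_index=r_sample, beat_class=cls))
        prev_t = t_beat
        return True

    t = 0.6
    while t < config.duration_s:
        clock = start_time + timedelta(seconds=t)
        hr = diurnal_rate(clock, config.mean_hr_day + hr_offset,
                          config.mean_hr_night + hr_offset)
        night = _night_weight(clock.hour + clock.minute / 60.0
                              + clock.second / 3600.0) > 0.5
        rr = (60.0 / hr) * float(np.exp(rng.normal(0.0, config.rr_jitter_sigma)))
        place(t, BeatClass.NORMAL, night)
        lam = (sve_rate + ve_rate) / 3600.0
        if lam > 0 and rng.random() < 1.0 - math.exp(-lam * rr):
            is_sve = rng.random() < sve_rate / (sve_rate + ve_rate)
            cls = BeatClass.SVE if is_sve else BeatClass.VE
            coupling = rng.uniform(0.60, 0.70) * rr
            place(t + coupling, cls, night)
            t += 2.0 * rr  # compensatory pause
        else:
            t += rr

    if n_skipped:
        import logging
        logging.getLogger(__name__).info(
            "%s: skipped %d overlapping beats", patient_id, n_skipped)

    signal += rng.normal(0.0, config.noise_sd, size=signal.shape)
    rec = HolterRecording(
        patient_id=patient_id,
        signal=signal,
        fs=fs,
        channel_names=["mod_V5", "mod_V1", "lead_III"],
        start_time=start_time,
    )
    annotations.sort(key=lambda a: a.sample_index)
    return rec, annotations


# ---------------------------------------------------------------------------
# Cohort


def generate_cohort(
    config: SimConfig,
    outdir: str | Path | None = None,
) -> tuple[CohortManifest, dict[str, tuple[HolterRecording, list[BeatAnnotation]]]]:
    """Generate a labelled cohort; optionally persist it as WFDB files + CSV.

    ``round(n_patients * paf_fraction)`` patients are pAF-labelled; the
    assignment is a seeded permutation.  pAF patients receive an index date
    such that elapsed time (exam minus index) is log-uniform over
    ``[elapsed_months_low, elapsed_months_high]`` months, spanning the
    elapsed-time cutoff strata {3, 6, 12, 36}.  The entire cohort is a pure
    function of the config, including its seed.
    """
    rng = np.random.default_rng(config.seed)
    n_paf = int(round(config.n_patients * config.paf_fraction))
    labels = np.zeros(config.n_patients, dtype=bool)
    labels[rng.permutation(config.n_patients)[:n_paf]] = True

    exam_date = datetime.fromisoformat(config.exam_date)
    clk = datetime.strptime(config.start_clock, "%H:%M:%S")
    start_time = exam_date.replace(hour=clk.hour, minute=clk.minute,
                                   second=clk.second)

    patients: list[PatientRecord] = []
    data: dict[str, tuple[HolterRecording, list[BeatAnnotation]]] = {}
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        is_paf = bool(labels[i])
        if is_paf:
            lo, hi = config.elapsed_months_low, config.elapsed_months_high
            elapsed_m = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            index_date = exam_date - timedelta(days=elapsed_m * DAYS_PER_MONTH)
        else:
            index_date = None
        prng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        rec, anns = generate_patient_recording(
            pid, config, prng, is_paf, start_time=start_time
        )
        data[pid] = (rec, anns)
        rec_path = f"{pid}"
        patients.append(
            PatientRecord(
                patient_id=pid,
                paf_label=is_paf,
                index_date=index_date,
                exam_date=exam_date,
                record_path=rec_path,
                annotation_path=f"{pid}.atr",
            )
        )

    manifest = CohortManifest(patients=patients)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for p in manifest:
            rec, anns = data[p.patient_id]
            write_record(rec, anns, outdir / p.patient_id)
        write_cohort_manifest(manifest, outdir / "manifest.csv")
    return manifest, data
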