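"""Reading and writing Holter records, beat annotations, and cohort manifests.

Records are stored in the WFDB/MIT convention: a text header (``<record>.hea``),
a 16-bit little-endian signal file (``<record>.dat``, format 16, frame-
interleaved), and a beat annotation file (``<record>.atr``) using the MIT
annotation byte-pair encoding.  Only the subset of the format the pipeline
needs is supported: format 16, per-channel decimal gain with integer baseline,
base time/date in the record line.  Real and synthetic data flow through the
same paths.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BeatClass",
    "BeatAnnotation",
    "HolterRecording",
    "PatientRecord",
    "CohortManifest",
    "read_record",
    "write_record",
    "read_annotations",
    "read_cohort_manifest",
    "write_cohort_manifest",
    "SYMBOL_TO_CLASS",
]


class BeatClass(str, Enum):
    """Three-way beat taxonomy used throughout the pipeline."""

    NORMAL = "NORMAL"
    SVE = "SVE"          # supraventricular ectopy (premature atrial complex)
    VE = "VE"            # ventricular ectopy
    OTHER = "OTHER"


# WFDB beat annotation codes (subset).  The dialect is a declared convention:
# N/L/R -> NORMAL, S/A/a/J -> SVE, V -> VE, everything else -> OTHER.
_SYMBOL_CODES = {
    "N": 1, "L": 2, "R": 3, "a": 4, "V": 5, "F": 6, "J": 7, "A": 8,
    "S": 9, "E": 10, "j": 11, "/": 12, "Q": 13,
}
_CODE_SYMBOLS = {v: k for k, v in _SYMBOL_CODES.items()}

SYMBOL_TO_CLASS: dict[str, BeatClass] = {
    "N": BeatClass.NORMAL, "L": BeatClass.NORMAL, "R": BeatClass.NORMAL,
    "S": BeatClass.SVE, "A": BeatClass.SVE, "a": BeatClass.SVE,
    "J": BeatClass.SVE,
    "V": BeatClass.VE,
}

_CLASS_TO_SYMBOL = {
    BeatClass.NORMAL: "N",
    BeatClass.SVE: "A",
    BeatClass.VE: "V",
    BeatClass.OTHER: "Q",
}


@dataclass
class BeatAnnotation:
    """A single annotated beat: sample location plus class label."""

    sample_index: int
    beat_class: BeatClass
    symbol: str = ""

    def __post_init__(self) -> None:
        self.sample_index = int(self.sample_index)
        self.beat_class = BeatClass(self.beat_class)
        if self.sample_index < 0:
            raise ValueError("sample_index must be >= 0")
        if not self.symbol:
            self.symbol = _CLASS_TO_SYMBOL[self.beat_class]


@dataclass
class HolterRecording:
    """Multi-channel sampled ECG with clock anchoring.

    ``signal`` is ``(n_channels, n_samples)`` in millivolts; sample ``k``
    corresponds to clock time ``start_time + k / fs``.
    """

    patient_id: str
    signal: np.ndarray
    fs: float
    channel_names: list[str]
    start_time: datetime

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (n_channels, n_samples)")
        if self.signal.shape[1] < 1:
            raise ValueError("signal must contain at least one sample")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if np.isnan(self.signal).any():
            raise ValueError("signal contains missing values")
        if self.n_channels != 3:
            logger.warning(
                "record %s has %d channels; pipeline expects 3",
                self.patient_id, self.n_channels,
            )

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def time_of_sample(self, k: int) -> datetime:
        return self.start_time + timedelta(seconds=k / self.fs)

    def sample_of_time(self, t: datetime) -> int:
        return int(round((t - self.start_time).total_seconds() * self.fs))


@dataclass
class PatientRecord:
    """One manifest row: patient identity, outcome label and record paths."""

    patient_id: str
    paf_label: bool
    exam_date: datetime
    index_date: datetime | None = None
    record_path: str = ""
    annotation_path: str = ""
    fold: int | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.paf_label and self.index_date is None:
            raise ValueError(
                f"pAF patient {self.patient_id!r} must carry an index_date"
            )


@dataclass
class CohortManifest:
    """Validated collection of :class:`PatientRecord` rows."""

    patients: list[PatientRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.paf_label for p in self.patients], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [p.patient_id for p in self.patients],
                "paf_label": [p.paf_label for p in self.patients],
                "index_date": [
                    p.index_date.date().isoformat() if p.index_date else ""
                    for p in self.patients
                ],
                "exam_date": [p.exam_date.date().isoformat() for p in self.patients],
                "record_path": [p.record_path for p in self.patients],
                "annotation_path": [p.annotation_path for p in self.patients],
            }
        )


# ---------------------------------------------------------------------------
# WFDB header + signal


def _fmt_gain(g: float) -> str:
    return f"{g:.6g}"


def write_record(
    recording: HolterRecording,
    annotations: list[BeatAnnotation],
    path: str | os.PathLike,
) -> None:
    """Write ``<path>.hea`` / ``<path>.dat`` (format 16) and ``<path>.atr``.

    Per-channel gain is chosen so the digitised signal spans most of the
    16-bit range; baseline is 0.  Round-trip error is bounded by half a
    quantisation step (1 / gain) per channel.
    """
    path = Path(path)
    rec = recording
    name = path.name
    path.parent.mkdir(parents=True, exist_ok=True)

    gains = []
    digital = np.empty_like(rec.signal, dtype=np.int16)
    for c in range(rec.n_channels):
        maxabs = float(np.max(np.abs(rec.signal[c]))) if rec.n_samples else 0.0
        gain = 30000.0 / maxabs if maxabs > 1e-12 else 200.0
        gain = float(min(max(gain, 1.0), 1e6))
        gains.append(gain)
        digital[c] = np.round(rec.signal[c] * gain).astype(np.int16)

    lines = [
        f"{name} {rec.n_channels} {_fmt_gain(rec.fs)} {rec.n_samples} "
        f"{rec.start_time:%H:%M:%S} {rec.start_time:%d/%m/%Y}"
    ]
    for c in range(rec.n_channels):
        lines.append(
            f"{name}.dat 16 {_fmt_gain(gains[c])}(0)/mV 16 0 "
            f"{int(digital[c, 0])} 0 0 {rec.channel_names[c]}"
        )
    (path.parent / f"{name}.hea").write_text("\n".join(lines) + "\n")

    # frame-interleaved int16 little-endian
    digital.T.astype("<i2").tofile(path.parent / f"{name}.dat")

    _write_atr(path.parent / f"{name}.atr", annotations)


def read_record(path: str | os.PathLike) -> HolterRecording:
    """Read a WFDB format-16 record (``<path>.hea`` + ``.dat``).

    Amplitudes are returned in physical units via ``(digital - baseline)/gain``.
    """
    path = Path(path)
    hea = path.with_suffix(".hea") if path.suffix != ".hea" else path
    base = hea.with_suffix("")
    if not hea.exists():
        raise FileNotFoundError(f"missing WFDB header: {hea}")
    lines = [
        ln.strip() for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    if len(head) < 4:
        raise ValueError(f"corrupt WFDB header (record line): {hea}")
    n_sig = int(head[1])
    fs = float(head[2].split("/")[0])
    n_samples = int(head[3])
    if len(head) >= 6:
        start_time = datetime.strptime(
            head[5] + " " + head[4].split(".")[0], "%d/%m/%Y %H:%M:%S"
        )
    elif len(head) == 5:
        t = datetime.strptime(head[4].split(".")[0], "%H:%M:%S")
        start_time = datetime(2000, 1, 1, t.hour, t.minute, t.second)
    else:
        start_time = datetime(2000, 1, 1)

    if len(lines) < 1 + n_sig:
        raise ValueError(f"corrupt WFDB header (signal lines): {hea}")
    gains, baselines, names, fmts = [], [], [], []
    for ln in lines[1 : 1 + n_sig]:
        f = ln.split()
        fmts.append(f[1].split("x")[0].split(":")[0].split("+")[0])
        gspec = f[2] if len(f) > 2 else "200"
        g = gspec.split("/")[0]
        if "(" in g:
            gain_s, base_s = g.split("(")
            baselines.append(int(base_s.rstrip(")")))
        else:
            gain_s = g
            baselines.append(int(f[4]) if len(f) > 4 else 0)
        gains.append(float(gain_s) if float(gain_s) != 0 else 200.0)
        names.append(f[8] if len(f) > 8 else f"ch{len(names)}")
    if any(fmt != "16" for fmt in fmts):
        raise ValueError(f"unsupported WFDB signal format (only 16): {hea}")

    raw = np.fromfile(base.parent / f"{base.name}.dat", dtype="<i2")
    if n_samples == 0:
        n_samples = raw.size // n_sig
    raw = raw[: n_samples * n_sig].reshape(n_samples, n_sig).T.astype(float)
    signal = (raw - np.array(baselines)[:, None]) / np.array(gains)[:, None]

    if n_sig != 3:
        logger.warning("record %s: %d channels, expected 3", base.name, n_sig)
    return HolterRecording(
        patient_id=base.name,
        signal=signal,
        fs=fs,
        channel_names=names,
        start_time=start_time,
    )


# ---------------------------------------------------------------------------
# MIT annotation files


def _write_atr(path: Path, annotations: list[BeatAnnotation]) -> None:
    """Encode annotations as MIT byte pairs (code in top 6 bits, delta in 10).

    Intervals >= 1024 samples use a SKIP (code 59) word followed by the
    interval as a 32-bit value, most-significant 16-bit word first, each word
    little-endian; the annotation word then carries a zero delta.
    """
    anns = sorted(annotations, key=lambda a: a.sample_index)
    out = bytearray()
    prev = 0
    for a in anns:
        code = _SYMBOL_CODES.get(a.symbol or _CLASS_TO_SYMBOL[a.beat_class], 13)
        delta = a.sample_index - prev
        if delta < 0:
            raise ValueError("annotations must be sorted by sample_index")
        if delta >= 1024:
            out += int(59 << 10).to_bytes(2, "little")
            out += ((delta >> 16) & 0xFFFF).to_bytes(2, "little")
            out += (delta & 0xFFFF).to_bytes(2, "little")
            delta = 0
        out += ((code << 10) | delta).to_bytes(2, "little")
        prev = a.sample_index
    out += (0).to_bytes(2, "little")  # EOF
    path.write_bytes(bytes(out))


def read_annotations(
    path: str | os.PathLike, n_samples: int | None = None
) -> list[BeatAnnotation]:
    """Read an MIT annotation file and map symbols to beat classes.

    Mapping (fixed convention): N/L/R -> NORMAL, S/A/a/J -> SVE, V -> VE,
    everything else -> OTHER.  Annotations outside ``[0, n_samples)`` are
    dropped with a logged warning; output is sorted by sample index.
    """
    path = Path(path)
    data = path.read_bytes()
    anns: list[BeatAnnotation] = []
    t = 0
    i = 0
    pending_skip = 0
    while i + 1 < len(data) or (i + 1 == len(data) + 1):
        if i + 2 > len(data):
            break
        word = int.from_bytes(data[i : i + 2], "little")
        i += 2
        code = word >> 10
        delta = word & 0x3FF
        if word == 0:
            break  # EOF
        if code == 59:  # SKIP: 4-byte long interval, high word first
            hi = int.from_bytes(data[i : i + 2], "little")
            lo = int.from_bytes(data[i + 2 : i + 4], "little")
            i += 4
            pending_skip += (hi << 16) + lo
            continue
        if code in (60, 61, 62, 63):  # NUM/SUB/CHN/AUX modifiers: skip payload
            if code == 63:
                n = delta + (delta & 1)
                i += n
            continue
        t += delta + pending_skip
        pending_skip = 0
        symbol = _CODE_SYMBOLS.get(code, "Q")
        cls = SYMBOL_TO_CLASS.get(symbol, BeatClass.OTHER)
        anns.append(BeatAnnotation(sample_index=t, beat_class=cls, symbol=symbol))

    anns.sort(key=lambda a: a.sample_index)
    if n_samples is not None:
        kept = [a for a in anns if a.sample_index < n_samples]
        if len(kept) != len(anns):
            logger.warning(
                "%s: dropped %d annotations beyond %d samples",
                path.name, len(anns) - len(kept), n_samples,
            )
        anns = kept
    return anns


# ---------------------------------------------------------------------------
# Cohort manifest

_MANIFEST_COLUMNS = [
    "patient_id", "paf_label", "index_date",
    "exam_date", "record_path", "annotation_path",
]

_TRUE_STRINGS = {"true", "1", "yes", "t"}


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer, float)):
        return bool(int(x))
    return str(x).strip().lower() in _TRUE_STRINGS


def read_cohort_manifest(path: str | os.PathLike) -> CohortManifest:
    """Read and validate a cohort manifest CSV (ISO-8601 dates).

    Raises on duplicate patient ids and on pAF rows with a blank index date;
    controls may leave ``index_date`` empty.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    patients = []
    for _, row in df.iterrows():
        paf = _parse_bool(row["paf_label"])
        idx = row["index_date"].strip()
        index_date = datetime.fromisoformat(idx) if idx else None
        if paf and index_date is None:
            raise ValueError(
                f"pAF patient {row['patient_id']!r} has no index_date"
            )
        patients.append(
            PatientRecord(
                patient_id=row["patient_id"],
                paf_label=paf,
                index_date=index_date,
                exam_date=datetime.fromisoformat(row["exam_date"]),
                record_path=row["record_path"],
                annotation_path=row["annotation_path"],
            )
        )
    return CohortManifest(patients=patients)


def write_cohort_manifest(manifest: CohortManifest, path: str | os.PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    manifest.to_frame().to_csv(path, index=False)
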