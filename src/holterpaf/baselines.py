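"""SVE-burden baseline: the comparator the two-stage model must beat.

The burden of supraventricular ectopy is the fraction of a patient's
retained 7-s segments that contain at least one SVE beat; it is used
directly as the pAF ranking score.  Burden must be computed from setting-1
preprocessing (SVE retained) — setting 2 removes the signal by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .preprocess import EcgSegment

logger = logging.getLogger(__name__)

__all__ = ["BurdenScore", "sve_burden_score"]


@dataclass
class BurdenScore:
    patient_id: str
    burden: float
    n_sve_segments: int
    n_total_segments: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.burden <= 1.0:
            raise ValueError("burden must be in [0, 1]")


def sve_burden_score(segments: list[EcgSegment]) -> BurdenScore | None:
    """Fraction of segments flagged ``contains_sve`` for one patient.

    Returns None (patient excluded, warning logged) when the patient has no
    retained segments, where burden is undefined.
    """
    if not segments:
        logger.warning("patient with zero segments excluded from SVE burden")
        return None
    pid = segments[0].patient_id
    if any(s.patient_id != pid for s in segments):
        raise ValueError("sve_burden_score expects segments of one patient")
    n_sve = sum(1 for s in segments if s.contains_sve)
    return BurdenScore(
        patient_id=pid,
        burden=n_sve / len(segments),
        n_sve_segments=n_sve,
        n_total_segments=len(segments),
    )
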