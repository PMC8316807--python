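"""Vocal bout segmentation and hourly vocal rates.

A vocal bout is all of an individual's vocalizations within 30 s of one
another: consecutive events chain into the same bout while the gap between
them is at most the inter-bout interval (single linkage; a gap of exactly
30 s stays in the bout).  Bouts never chain across focal sessions — a bout
cannot span unobserved time.  An individual's rate is bouts per focal hour
and enters the analyses only with at least 2 h of focal observation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tables import FocalSession, ValidationError, VocalEvent

DEFAULT_IBI_SECONDS = 30.0
DEFAULT_MIN_FOCAL_HOURS = 2.0


def segment_bouts(times: Sequence[float], ibi: float = DEFAULT_IBI_SECONDS) -> int:
    """Number of vocal bouts in a sorted event-time sequence.

    A new bout starts at each event whose gap from the previous event
    exceeds ``ibi`` (gap == ibi chains).
    """
    if ibi <= 0:
        raise ValidationError(f"ibi must be > 0, got {ibi}")
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return 0
    gaps = np.diff(t)
    if np.any(gaps < 0):
        raise ValidationError("event times must be sorted ascending")
    return int(1 + np.sum(gaps > ibi))


@dataclass(frozen=True)
class VocalRateRecord:
    """Per-individual vocal output: bout count, observation time and rate."""

    focal_id: str
    group_id: str
    n_bouts: int
    obs_hours: float
    rate: float           # bouts per hour
    included: bool        # obs_hours >= the 2-h minimum


def vocal_rate(events: Sequence[VocalEvent], sessions: Sequence[FocalSession],
               focal_id: str, ibi: float = DEFAULT_IBI_SECONDS,
               min_focal_hours: float = DEFAULT_MIN_FOCAL_HOURS) -> VocalRateRecord:
    """Hourly vocal bout rate of one focal individual.

    Events are segmented within each session independently (no chaining
    across sessions); observation time is the summed session duration.
    """
    own_sessions = sorted((s for s in sessions if s.focal_id == focal_id),
                          key=lambda s: s.start)
    if not own_sessions:
        raise ValidationError(f"no focal sessions for {focal_id}")
    own_times = sorted(e.time for e in events if e.focal_id == focal_id)

    n_bouts = 0
    for s in own_sessions:
        in_session = [t for t in own_times if s.start <= t <= s.end]
        n_bouts += segment_bouts(in_session, ibi=ibi)

    obs_hours = sum(s.duration for s in own_sessions)
    group_id = own_sessions[0].group_id
    return VocalRateRecord(
        focal_id=focal_id, group_id=group_id, n_bouts=n_bouts,
        obs_hours=obs_hours, rate=n_bouts / obs_hours,
        included=obs_hours >= min_focal_hours)
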