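"""From capacitance samples to licks.

A capacitive lickometer registers a *touch* when the filtered sensor reading
jumps up by at least ``delta`` counts relative to the previous reading and a
*release* when it drops by at least ``delta`` (default 12, the MPR121-style
threshold).  The rule is applied per consecutive sample pair — a slow ramp
below ``delta`` per step emits nothing — and a state machine forces touch and
release to alternate, starting from the untouched state.

Touch/release events are then paired into licks (onset = touch time,
duration = release − touch) and filtered on duration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .event_io import RELEASE, TOUCH, RawEvent

_log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Touch-detection threshold.

    ``delta`` is in raw sensor counts; ``sample_period`` (seconds per sample)
    is carried as metadata for generators and round-trip checks, not used by
    detection itself.
    """

    delta: int = 12
    sample_period: float | None = None

    def __post_init__(self):
        if self.delta < 1:
            raise ValidationError(f"delta must be >= 1, got {self.delta}")


@dataclass(frozen=True)
class Lick:
    """One tongue-spout contact: onset time and contact duration, seconds."""

    onset: float
    duration: float
    channel: int = 0
    session_id: str = ""

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError(
                f"lick duration must be > 0, got {self.duration}"
            )

    @property
    def end(self) -> float:
        return self.onset + self.duration


def detect_transitions(
    times: Sequence[float],
    values: Sequence[float],
    params: DetectionParams = DetectionParams(),
) -> list[RawEvent]:
    """Apply the per-step delta rule to a single channel's sample stream.

    Emits a touch where ``value[i] - value[i-1] >= delta`` and a release
    where ``value[i-1] - value[i] >= delta``, collapsing consecutive
    same-polarity triggers to the first (the state machine must alternate,
    starting untouched; a release trigger before any touch is suppressed).
    The event timestamp is that of the triggering sample.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValidationError("times and values must have equal length")
    if t.size and np.any(np.diff(t) <= 0):
        raise ValidationError("sample timestamps must be strictly increasing")
    if t.size < 2:
        return []
    dv = np.diff(v)
    # Only steps crossing the threshold matter; iterate those, not every sample.
    (idx,) = np.nonzero(np.abs(dv) >= params.delta)
    events: list[RawEvent] = []
    touched = False
    for i in idx:
        if dv[i] >= params.delta and not touched:
            events.append(RawEvent(float(t[i + 1]), 0, TOUCH, int(round(v[i + 1]))))
            touched = True
        elif dv[i] <= -params.delta and touched:
            events.append(RawEvent(float(t[i + 1]), 0, RELEASE, int(round(v[i + 1]))))
            touched = False
    return events


def build_licks(
    events: Sequence[RawEvent], session_id: str = "", channel: int | None = None
) -> list[Lick]:
    """Pair touch/release events into licks.

    Each touch is paired with the next release on the channel.  Orphans are
    handled conservatively (never inventing contact time) and logged, not
    fatal: a release before any touch is dropped; on a double touch the
    earlier one (farther from the eventual release) is dropped; a trailing
    touch with no release is dropped.
    """
    if events:
        channels = {ev.channel for ev in events}
        if len(channels) > 1:
            raise ValidationError(
                f"build_licks expects a single channel, got {sorted(channels)}"
            )
        ts = [ev.t for ev in events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValidationError("events must be time-ordered")
        if channel is None:
            channel = events[0].channel
    licks: list[Lick] = []
    pending: RawEvent | None = None
    for ev in events:
        if ev.polarity == TOUCH:
            if pending is not None:
                _log.warning(
                    "session %s: double touch at %.3f s; dropping earlier touch "
                    "at %.3f s", session_id, ev.t, pending.t,
                )
            pending = ev
        else:
            if pending is None:
                _log.warning(
                    "session %s: release at %.3f s with no preceding touch; "
                    "dropped", session_id, ev.t,
                )
                continue
            duration = ev.t - pending.t
            if duration <= 0:
                _log.warning(
                    "session %s: zero-duration contact at %.3f s; dropped",
                    session_id, pending.t,
                )
            else:
                licks.append(Lick(pending.t, duration, channel or 0, session_id))
            pending = None
    if pending is not None:
        _log.warning(
            "session %s: touch at %.3f s with no release before session end; "
            "dropped", session_id, pending.t,
        )
    return licks


def filter_licks(
    licks: Sequence[Lick],
    min_duration: float = 0.005,
    max_duration: float = 10.0,
) -> list[Lick]:
    """Keep licks with ``min_duration <= duration <= max_duration``.

    The default bounds are deliberately permissive: the lower bound rejects
    sub-5-ms contact glitches, while the 10 s ceiling is far above any
    physiological lick so that genuinely long spout contacts (which carry the
    non-bout-duration phenotype) are never truncated.
    """
    if not (0 <= min_duration < max_duration):
        raise ValidationError(
            f"need 0 <= min_duration < max_duration, got "
            f"({min_duration}, {max_duration})"
        )
    kept = [lk for lk in licks if min_duration <= lk.duration <= max_duration]
    removed = len(licks) - len(kept)
    if removed:
        _log.info("filter_licks removed %d of %d licks", removed, len(licks))
    return kept


def dedupe_onsets(
    licks: Sequence[Lick], quantum: float = 1e-3
) -> list[Lick]:
    """Enforce strictly increasing onsets by bumping duplicates one quantum.

    Duplicate timestamps (possible after clock quantisation) are invalid
    input for bout segmentation; each duplicate is shifted forward by the
    millisecond timestamp quantum and logged.
    """
    out: list[Lick] = []
    bumped = 0
    last = -np.inf
    for lk in sorted(licks, key=lambda l: l.onset):
        onset = lk.onset
        if onset <= last:
            onset = last + quantum
            bumped += 1
        out.append(Lick(onset, lk.duration, lk.channel, lk.session_id))
        last = onset
    if bumped:
        _log.warning("bumped %d duplicate lick onsets by %g s", bumped, quantum)
    return out
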