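"""Per-session drinking-microstructure summaries and temporal analyses.

Summaries cover total licks, total contact time, bout counts, licks per
bout, contact time per bout, the percentage of licks occurring inside bouts,
and mean contact durations split by bout membership.  Temporal analyses
cover cumulative lick curves, the frontloading split (first 30 min of the
session by default, half-open ``[0, window)``), and pooled per-group time /
cumulative-count distributions ready for Kolmogorov-Smirnov comparison and
kernel-density estimation.

Means over empty sets are NaN sentinels, never zero — a session with no
bouts has an undefined licks-per-bout, not zero licks per bout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np

from .bout_segmentation import Bout
from .errors import ValidationError
from .event_io import NONBOUT, SessionRecord
from .lick_processing import Lick


@dataclass(frozen=True)
class TemporalParams:
    """Windows and KDE settings for temporal analyses.

    ``frontload_window`` is the length, in seconds, of the initial session
    window used for the frontloading split (default 1800 s = 30 min).
    """

    frontload_window: float = 1800.0
    kde_grid_points: int = 256
    kde_bandwidth_rule: str = "scott"

    def __post_init__(self):
        if self.frontload_window <= 0:
            raise ValidationError("frontload_window must be > 0")
        if self.kde_bandwidth_rule not in ("scott", "silverman", "fixed"):
            raise ValidationError(
                f"unknown bandwidth rule {self.kde_bandwidth_rule!r}"
            )


@dataclass
class MicrostructureSummary:
    session_id: str
    total_licks: int
    total_lick_duration: float
    n_bouts: int
    licks_per_bout: float          # NaN when no bouts
    lick_duration_per_bout: float  # mean total contact time per bout; NaN when no bouts
    pct_licks_in_bouts: float
    n_nonbout_licks: int
    mean_lick_duration_bout: float     # NaN when no bout licks
    mean_lick_duration_nonbout: float  # NaN when no non-bout licks
    licks_frontload: int
    licks_postfrontload: int
    intake: float = math.nan  # g/kg, joined from intake_pk

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_session(
    licks: Sequence[Lick],
    bouts: Sequence[Bout],
    labels: Sequence[str],
    session: SessionRecord,
    params: TemporalParams = TemporalParams(),
) -> MicrostructureSummary:
    """Compute the per-session microstructure summary.

    ``labels`` must be the per-lick membership labels produced by
    :func:`lickstruct.bout_segmentation.label_licks` for these bouts.
    """
    if len(labels) != len(licks):
        raise ValidationError(
            f"{len(labels)} labels for {len(licks)} licks"
        )
    if params.frontload_window >= session.session_length:
        raise ValidationError(
            "frontload_window must be shorter than the session"
        )
    for lk in licks:
        if not (0 <= lk.onset <= session.session_length):
            raise ValidationError(
                f"session {session.session_id}: lick onset {lk.onset} outside "
                f"[0, {session.session_length}]"
            )
    total = len(licks)
    durations = np.array([lk.duration for lk in licks], dtype=float)
    is_bout = np.array([lab != NONBOUT for lab in labels], dtype=bool)
    n_bout_licks = int(is_bout.sum())
    n_bouts = len(bouts)
    onsets = np.array([lk.onset for lk in licks], dtype=float)
    front, post = frontload_split(onsets, params)

    def _mean(arr) -> float:
        return float(np.mean(arr)) if len(arr) else math.nan

    bout_totals = []
    for bout in bouts:
        if bout.total_lick_duration is not None:
            bout_totals.append(bout.total_lick_duration)
        else:
            bout_totals.append(sum(licks[i].duration for i in bout.lick_indices))
    return MicrostructureSummary(
        session_id=session.session_id,
        total_licks=total,
        total_lick_duration=float(durations.sum()),
        n_bouts=n_bouts,
        licks_per_bout=_mean([b.n_licks for b in bouts]),
        lick_duration_per_bout=_mean(bout_totals),
        pct_licks_in_bouts=(100.0 * n_bout_licks / total) if total else 0.0,
        n_nonbout_licks=total - n_bout_licks,
        mean_lick_duration_bout=_mean(durations[is_bout]),
        mean_lick_duration_nonbout=_mean(durations[~is_bout]),
        licks_frontload=front,
        licks_postfrontload=post,
    )


def cumulative_curve(
    onsets: Sequence[float], grid: Sequence[float]
) -> np.ndarray:
    """Cumulative lick count at each grid point (onset <= g, inclusive)."""
    x = np.sort(np.asarray(onsets, dtype=float))
    g = np.asarray(grid, dtype=float)
    if g.size and np.any(np.diff(g) < 0):
        raise ValidationError("grid must be sorted")
    return np.searchsorted(x, g, side="right")


def frontload_split(
    onsets: Sequence[float], params: TemporalParams = TemporalParams()
) -> tuple[int, int]:
    """Count licks in the half-open frontloading window vs the rest.

    A lick at exactly the window boundary is post-frontload; the two counts
    always sum to the total.
    """
    x = np.asarray(onsets, dtype=float)
    front = int(np.count_nonzero(x < params.frontload_window))
    return front, int(x.size) - front


def pooled_time_distribution(
    group_sessions: Mapping[str, Sequence[Sequence[float]]],
) -> dict[str, dict[str, np.ndarray]]:
    """Pool lick onsets and within-session cumulative counts per group.

    ``group_sessions`` maps a group key to a list of per-session onset
    sequences.  For each group, returns the pooled multiset of onset times
    and of within-session cumulative lick indices (1..n per session), the
    two marginals compared by genotype with KS tests.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for group, sessions in group_sessions.items():
        if len(sessions) == 0:
            raise ValidationError(f"group {group!r} has no sessions")
        times: list[np.ndarray] = []
        cumulative: list[np.ndarray] = []
        for onsets in sessions:
            x = np.sort(np.asarray(onsets, dtype=float))
            times.append(x)
            cumulative.append(np.arange(1, x.size + 1, dtype=float))
        out[group] = {
            "times": np.concatenate(times) if times else np.empty(0),
            "cumulative": np.concatenate(cumulative) if cumulative else np.empty(0),
        }
    return out
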