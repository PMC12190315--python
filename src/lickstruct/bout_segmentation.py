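"""Partition a session's licks into bouts and non-bout licks.

A bout initiates at the first lick of a run of ``init_n`` licks (default 3)
whose consecutive inter-lick intervals are all at most ``init_ili_max``
(default 1 s), and terminates when no lick follows within ``term_gap``
(default 3 s) of the previous lick.  "Within 1 second of each other" is read
as consecutive inter-lick intervals, not a sliding window; boundary
comparisons are inclusive (an interval of exactly 1.0 s can initiate, a gap
of exactly 3.0 s continues a bout, and termination requires a gap strictly
greater than ``term_gap``).  Licks preceding the initiating run never
retro-join the bout: a single forward pass fully determines the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InternalConsistencyError, ValidationError
from .event_io import NONBOUT
from .lick_processing import Lick


@dataclass(frozen=True)
class SegmentationParams:
    """Bout initiation/termination criteria (seconds)."""

    init_n: int = 3
    init_ili_max: float = 1.0
    term_gap: float = 3.0

    def __post_init__(self):
        if self.init_n < 2:
            raise ValidationError(f"init_n must be >= 2, got {self.init_n}")
        if not (0 < self.init_ili_max <= self.term_gap):
            raise ValidationError(
                f"need 0 < init_ili_max <= term_gap, got "
                f"({self.init_ili_max}, {self.term_gap})"
            )


@dataclass
class Bout:
    """A maximal run of licks meeting the bout criteria.

    ``lick_indices`` index into the session lick sequence the bout was
    segmented from; they are contiguous and onset-sorted.
    """

    bout_id: int
    start: float
    end: float
    lick_indices: list[int]
    n_licks: int = field(init=False)
    total_lick_duration: float | None = None

    def __post_init__(self):
        self.n_licks = len(self.lick_indices)


def segment(
    onsets: Sequence[float], params: SegmentationParams = SegmentationParams()
) -> tuple[list[Bout], set[int]]:
    """Scan onsets left to right, returning (bouts, non-bout lick indices).

    The bout lick sets and the non-bout set partition the input.  Onsets must
    be strictly increasing (enforce upstream with
    :func:`lickstruct.lick_processing.dedupe_onsets`).
    """
    x = np.asarray(onsets, dtype=float)
    n = x.size
    if n and np.any(np.diff(x) <= 0):
        raise ValidationError("lick onsets must be strictly increasing")
    if n == 0:
        return [], set()
    ili = np.diff(x)
    # tight[i]: the init_n licks starting at i all have consecutive ILIs
    # <= init_ili_max (inclusive boundary).
    k = params.init_n - 1
    bouts: list[Bout] = []
    in_bout = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        if i + k < n and bool(np.all(ili[i : i + k] <= params.init_ili_max)):
            j = i + k
            while j + 1 < n and ili[j] <= params.term_gap:
                j += 1
            idx = list(range(i, j + 1))
            bouts.append(Bout(len(bouts), float(x[i]), float(x[j]), idx))
            in_bout[i : j + 1] = True
            i = j + 1
        else:
            i += 1
    nonbout = set(np.nonzero(~in_bout)[0].tolist())
    return bouts, nonbout


def label_licks(licks: Sequence[Lick], bouts: Sequence[Bout]) -> list[str]:
    """Per-lick membership labels: ``"b<id>"`` or the non-bout sentinel.

    Also fills each bout's ``total_lick_duration`` from the lick durations.
    """
    labels = [NONBOUT] * len(licks)
    for bout in bouts:
        total = 0.0
        for idx in bout.lick_indices:
            if not (0 <= idx < len(licks)):
                raise InternalConsistencyError(
                    f"bout {bout.bout_id} references lick index {idx} "
                    f"outside 0..{len(licks) - 1}"
                )
            if labels[idx] != NONBOUT:
                raise InternalConsistencyError(
                    f"lick {idx} assigned to two bouts"
                )
            labels[idx] = f"b{bout.bout_id}"
            total += licks[idx].duration
        bout.total_lick_duration = total
    return labels
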