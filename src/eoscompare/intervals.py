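"""Union-of-intervals bookkeeping for intermittent clinical findings.

Both decision engines measure how long an abnormality persists.  A vital is
considered abnormal from the observation at which it is measured abnormal
until the next observation at which that same vital is measured again; if it
is never re-measured, the abnormal interval ends at the last observation of
the timeline (persistence beyond the chart cannot be confirmed).  Durations
of intermittent findings accumulate over the union of abnormal intervals, so
splitting one abnormal interval into contiguous sub-intervals never changes
a decision.
"""

from __future__ import annotations

from typing import Optional, Sequence

__all__ = ["finding_intervals", "merge_intervals", "total_duration", "time_reaching"]


def merge_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping or touching half-open intervals."""
    out: list[tuple[float, float]] = []
    for start, end in sorted(intervals):
        if end <= start:
            continue
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def finding_intervals(
    times: Sequence[float],
    abnormal: Sequence[bool],
    measured: Optional[Sequence[bool]] = None,
) -> list[tuple[float, float]]:
    """Merged abnormal intervals for one finding over an observation timeline.

    Parameters
    ----------
    times : observation ages (strictly increasing, hours).
    abnormal : whether the finding was abnormal at each observation
        (only meaningful where ``measured`` is True).
    measured : whether the finding was assessed at each observation; defaults
        to all True (categorical flags are assessed at every observation).
    """
    n = len(times)
    if measured is None:
        measured = [True] * n
    if n == 0:
        return []
    last_time = times[-1]
    raw = []
    for i in range(n):
        if not (measured[i] and abnormal[i]):
            continue
        end = last_time
        for j in range(i + 1, n):
            if measured[j]:
                end = times[j]
                break
        raw.append((times[i], end))
    return merge_intervals(raw)


def total_duration(intervals: Sequence[tuple[float, float]]) -> float:
    return sum(end - start for start, end in intervals)


def time_reaching(
    intervals: Sequence[tuple[float, float]], duration: float
) -> Optional[float]:
    """Clock time at which cumulative union duration first reaches ``duration``.

    Returns None if the union never accumulates that much time.
    """
    acc = 0.0
    for start, end in merge_intervals(intervals):
        if acc + (end - start) >= duration:
            return start + (duration - acc)
        acc += end - start
    return None
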