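"""Congestion predicate and episode segmentation.

The hospital is congested at an hourly check when all three indicators hold
simultaneously: the ED admission side is nearly full (>= 17 of its 18 beds
occupied by default), inpatient bed occupancy is at or above 0.97 of
capacity, and at least 28 patients are queueing for ED treatment.  Maximal
runs of consecutive congested checks form congestion episodes, whose count
and durations are the primary outcome measures of every scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CongestionThresholds:
    """Joint thresholds of the hourly congestion predicate."""

    ed_min_occupied: int = 17
    inpatient_min_occupancy: float = 0.97
    queue_min: int = 28
    conjunctive: bool = True  # disjunctive mode exists only for sensitivity runs

    def __post_init__(self):
        if not 0.0 < self.inpatient_min_occupancy <= 1.0:
            raise ValueError("inpatient_min_occupancy must lie in (0, 1]")
        if self.queue_min < 0 or self.ed_min_occupied < 0:
            raise ValueError("count thresholds must be non-negative")


@dataclass(frozen=True)
class CongestionEpisode:
    """A maximal run of consecutive congested hourly checks.

    ``start`` is the hour index of the first congested check, ``end`` the
    first subsequent non-congested check (or the horizon for a run truncated
    by the end of the simulation).
    """

    start: int
    end: int

    @property
    def duration(self) -> int:
        return self.end - self.start


def is_congested(
    ed_occupied: int,
    inpatient_occupancy: float,
    queue_len: int,
    thresholds: CongestionThresholds = CongestionThresholds(),
) -> bool:
    """Evaluate the congestion predicate on one hourly state.

    All three criteria are inclusive (``>=``) and combined conjunctively by
    default.
    """
    checks = (
        ed_occupied >= thresholds.ed_min_occupied,
        inpatient_occupancy >= thresholds.inpatient_min_occupancy,
        queue_len >= thresholds.queue_min,
    )
    return all(checks) if thresholds.conjunctive else any(checks)


def congestion_flags(
    ed_occupied: np.ndarray,
    inpatient_occupancy: np.ndarray,
    queue_len: np.ndarray,
    thresholds: CongestionThresholds = CongestionThresholds(),
) -> np.ndarray:
    """Vectorised predicate over parallel hourly snapshot arrays."""
    c1 = np.asarray(ed_occupied) >= thresholds.ed_min_occupied
    c2 = np.asarray(inpatient_occupancy) >= thresholds.inpatient_min_occupancy
    c3 = np.asarray(queue_len) >= thresholds.queue_min
    if thresholds.conjunctive:
        return c1 & c2 & c3
    return c1 | c2 | c3


def extract_episodes(hourly_flags) -> list[CongestionEpisode]:
    """Segment an hourly boolean series into maximal congested runs.

    A run still open at the end of the series closes at the horizon, so its
    duration is the number of observed congested checks.
    """
    flags = np.asarray(hourly_flags, dtype=bool)
    if flags.size == 0:
        return []
    padded = np.concatenate([[False], flags, [False]]).astype(np.int8)
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [CongestionEpisode(int(s), int(e)) for s, e in zip(starts, ends)]


def episode_stats(episodes: list[CongestionEpisode]) -> tuple[int, float, float, float]:
    """(count, max duration, min duration, mean duration) in hours.

    An empty episode list reports zeros for the duration summaries.
    """
    if not episodes:
        return (0, 0.0, 0.0, 0.0)
    durations = np.array([e.duration for e in episodes], dtype=float)
    return (
        len(episodes),
        float(durations.max()),
        float(durations.min()),
        float(durations.mean()),
    )


def episodes_to_csv(episodes: list[CongestionEpisode], path, run_id: str = "") -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["run_id", "start_h", "end_h", "duration_h"])
        for e in episodes:
            w.writerow([run_id, e.start, e.end, e.duration])
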