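"""Scenario outcome metrics and the efficiency-per-affected-patient statistic.

Each simulation run is summarised over a collection window (by convention
the second simulated year) into a :class:`ScenarioMetrics` row: 10 AM
occupancy statistics, congestion-episode counts and durations, and the
counters of patients touched by the interventions.  Replications are
aggregated field-wise, and scenarios with patient-level actions are scored
by decongestion efficiency — the reduction in congestion events (or mean
congestion hours) relative to baseline, divided by the total number of
patients affected.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .congestion import episode_stats
from .engine import TrajectoryRecord, snapshot_10am_occupancy


@dataclass
class ScenarioMetrics:
    """One results-table row for a scenario (per collection year)."""

    mean_occupancy_10am: float = 0.0
    occupancy_std: float = 0.0
    n_congestion_events: float = 0.0
    max_congestion_h: float = 0.0
    min_congestion_h: float = 0.0
    mean_congestion_h: float = 0.0
    affected_patients: float = 0.0  # transfers + early discharges
    postponed_electives: float = 0.0
    diverted_ambulances: float = 0.0

    def validate(self) -> None:
        if self.n_congestion_events > 0 and not (
            self.min_congestion_h <= self.mean_congestion_h <= self.max_congestion_h
        ):
            raise ValueError("congestion duration summaries are inconsistent")
        for f in ("n_congestion_events", "affected_patients",
                  "postponed_electives", "diverted_ambulances"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


@dataclass
class EfficiencyResult:
    """Congestion reduction per affected patient, relative to baseline.

    Negative values mean the scenario worsened congestion.
    """

    event_efficiency: float
    time_efficiency: float
    total_affected: float


def summarize_run(
    trajectory: TrajectoryRecord, window: tuple[int, int]
) -> ScenarioMetrics:
    """Compute the metrics row from one run, restricted to ``window``.

    Episodes are attributed to the window by their start hour, with the full
    episode duration counted.  Intervention counters include events whose
    action time falls inside the window.
    """
    start, end = window
    if not (0 <= start < end <= trajectory.horizon):
        raise ValueError(f"window {window} outside horizon {trajectory.horizon}")

    mean_occ, std_occ = snapshot_10am_occupancy(trajectory, window)
    eps = [e for e in trajectory.episodes if start <= e.start < end]
    n_ev, mx, mn, mean_d = episode_stats(eps)

    transfers = discharges = 0
    for rec in trajectory.interventions:
        if start <= rec["time"] < end:
            transfers += rec.get("transfer", {}).get("actual", 0)
            discharges += rec.get("discharge", {}).get("actual", 0)
    postponed = int(np.count_nonzero(
        (trajectory.postpone_times >= start) & (trajectory.postpone_times < end)
    ))
    diverted = int(np.count_nonzero(
        (trajectory.divert_times >= start) & (trajectory.divert_times < end)
    ))

    m = ScenarioMetrics(
        mean_occupancy_10am=mean_occ,
        occupancy_std=std_occ,
        n_congestion_events=float(n_ev),
        max_congestion_h=mx,
        min_congestion_h=mn,
        mean_congestion_h=mean_d,
        affected_patients=float(transfers + discharges),
        postponed_electives=float(postponed),
        diverted_ambulances=float(diverted),
    )
    m.validate()
    return m


def aggregate_replications(metrics: list[ScenarioMetrics]) -> ScenarioMetrics:
    """Field-wise arithmetic mean over replications.

    Per-replication extrema (max/min congestion time) aggregate as the mean
    of the extrema, matching how replicated results tables report them.
    """
    if not metrics:
        raise ValueError("cannot aggregate an empty replication list")
    out = ScenarioMetrics()
    for f in fields(ScenarioMetrics):
        vals = [getattr(m, f.name) for m in metrics]
        setattr(out, f.name, float(np.mean(vals)))
    return out


def efficiency(
    baseline: ScenarioMetrics, scenario: ScenarioMetrics
) -> EfficiencyResult:
    """Decongestion efficiency of a scenario against the baseline.

    total affected = affected patients (transfers + discharges)
    + diverted ambulances + postponed electives.  Defined only for
    scenarios that touch patients; capacity-only scenarios raise.
    """
    total = (scenario.affected_patients + scenario.diverted_ambulances
             + scenario.postponed_electives)
    if total <= 0:
        raise ValueError(
            "efficiency undefined: scenario affects no patients "
            "(capacity-only scenarios have no per-patient efficiency)"
        )
    return EfficiencyResult(
        event_efficiency=(baseline.n_congestion_events
                          - scenario.n_congestion_events) / total,
        time_efficiency=(baseline.mean_congestion_h
                         - scenario.mean_congestion_h) / total,
        total_affected=total,
    )
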