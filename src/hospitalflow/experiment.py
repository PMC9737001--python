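"""Experiment orchestration: replications, aggregation, ranking, calibration.

A full experiment simulates each requested scenario for two years, discards
the first (warm-up) year, replicates with common random numbers — replication
r of every scenario uses seed ``base_seed + r``, so scenarios face identical
arrival and length-of-stay streams — and aggregates the second-year metrics.
Scenarios with patient-level actions additionally receive efficiency scores
against the baseline.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import HospitalConfig, default_config
from .congestion import CongestionThresholds
from .engine import HOURS_PER_YEAR, run_simulation
from .metrics import ScenarioMetrics, aggregate_replications, efficiency, summarize_run

RANK_KEYS = {
    "events": ("n_congestion_events", True),
    "mean_duration": ("mean_congestion_h", True),
    "max_duration": ("max_congestion_h", True),
    "event_efficiency": ("event_efficiency", False),
    "time_efficiency": ("time_efficiency", False),
}


@dataclass
class ExperimentPlan:
    """What to run: scenarios, replication count, horizon, seeding."""

    scenario_ids: tuple = tuple(range(27))
    replications: int = 20
    years: int = 2
    warmup_years: int = 1
    base_seed: int = 1
    output_dir: str | None = None
    hours: float | None = None  # overrides years for reduced-scale runs
    collect_start: float | None = None  # with hours: start of collection window

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.hours is None and not self.warmup_years < self.years:
            raise ValueError("warm-up must be shorter than the simulated horizon")

    @property
    def window(self) -> tuple[int, int]:
        if self.hours is not None:
            start = int(self.collect_start or 0)
            return (start, int(self.hours))
        return (self.warmup_years * HOURS_PER_YEAR, self.years * HOURS_PER_YEAR)


def run_scenario_replications(
    config: HospitalConfig,
    scenario_id: int,
    plan: ExperimentPlan,
    thresholds: CongestionThresholds | None = None,
) -> list[ScenarioMetrics]:
    """Per-replication second-year metrics for one scenario."""
    out = []
    for r in range(plan.replications):
        traj = run_simulation(
            config, scenario_id, years=plan.years, seed=plan.base_seed + r,
            thresholds=thresholds, hours=plan.hours,
        )
        out.append(summarize_run(traj, plan.window))
    return out


def run_experiment(
    plan: ExperimentPlan,
    config: HospitalConfig | None = None,
    thresholds: CongestionThresholds | None = None,
) -> pd.DataFrame:
    """Run the full scenario experiment and return the results table.

    One row per scenario: the aggregated metrics plus, for scenarios with
    patient-level actions, the two efficiency columns.  Efficiency scoring
    requires scenario 0 in the plan.  If ``plan.output_dir`` is set, writes
    ``results.csv`` and a provenance JSON sufficient to regenerate it.
    """
    if config is None:
        config = default_config()
    ids = list(plan.scenario_ids)
    wants_efficiency = any(i >= 13 for i in ids)
    if wants_efficiency and 0 not in ids:
        raise ValueError("scenario 0 (baseline) is required to score efficiencies")

    agg: dict[int, ScenarioMetrics] = {}
    for sid in ids:
        agg[sid] = aggregate_replications(
            run_scenario_replications(config, sid, plan, thresholds)
        )

    rows = []
    base = agg.get(0)
    for sid in ids:
        m = agg[sid]
        row = {"scenario": sid, **dataclasses.asdict(m)}
        touched = m.affected_patients + m.postponed_electives + m.diverted_ambulances
        if base is not None and sid != 0 and touched > 0:
            e = efficiency(base, m)
            row["event_efficiency"] = e.event_efficiency
            row["time_efficiency"] = e.time_efficiency
            row["total_affected"] = e.total_affected
        else:
            row["event_efficiency"] = np.nan
            row["time_efficiency"] = np.nan
            row["total_affected"] = touched
        rows.append(row)
    df = pd.DataFrame(rows).set_index("scenario")

    if plan.output_dir is not None:
        outdir = Path(plan.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / "results.csv", float_format="%.6f")
        provenance = {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "config": config.to_dict(),
            "plan": {
                "scenario_ids": ids,
                "replications": plan.replications,
                "years": plan.years,
                "warmup_years": plan.warmup_years,
                "base_seed": plan.base_seed,
                "hours": plan.hours,
                "collect_start": plan.collect_start,
            },
            "seeds": [plan.base_seed + r for r in range(plan.replications)],
        }
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
    return df


def rank_scenarios(results: pd.DataFrame, key: str = "events") -> list[int]:
    """Scenario ids ordered best-first by the chosen key.

    Congestion metrics rank ascending (fewer/shorter is better); efficiency
    metrics rank descending.  Ties break by scenario id; scenarios without
    a defined value for the key (e.g. capacity-only scenarios under an
    efficiency key) are dropped.
    """
    if key not in RANK_KEYS:
        raise ValueError(f"unknown ranking key {key!r}; valid: {sorted(RANK_KEYS)}")
    col, ascending = RANK_KEYS[key]
    s = results[col].dropna()
    order = sorted(
        s.index, key=lambda i: (s[i] if ascending else -s[i], i)
    )
    return [int(i) for i in order]


def calibrate_arrival_multiplier(
    target_events: float = 110.0,
    band: tuple = (50.0, 160.0),
    replications: int = 3,
    base_seed: int = 1,
    lo: float = 0.9,
    hi: float = 1.1,
    iterations: int = 6,
) -> dict:
    """Bisection search for the global arrival-intensity multiplier.

    Baseline congestion frequency rises monotonically with offered load, so
    the multiplier giving a target annual episode count is found by
    bisection on the mean second-year episode count over a few 2-year
    baseline replications.  Returns the search trace and chosen multiplier.
    """
    plan = ExperimentPlan(scenario_ids=(0,), replications=replications,
                          base_seed=base_seed)

    def events_at(m: float) -> float:
        cfg = default_config(arrival_multiplier=m)
        reps = run_scenario_replications(cfg, 0, plan)
        return aggregate_replications(reps).n_congestion_events

    trace = []
    e_lo, e_hi = events_at(lo), events_at(hi)
    trace += [(lo, e_lo), (hi, e_hi)]
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        e_mid = events_at(mid)
        trace.append((mid, e_mid))
        if e_mid < target_events:
            lo, e_lo = mid, e_mid
        else:
            hi, e_hi = mid, e_mid
    chosen = min(trace, key=lambda te: abs(te[1] - target_events))
    return {
        "multiplier": chosen[0],
        "events": chosen[1],
        "in_band": band[0] <= chosen[1] <= band[1],
        "trace": trace,
    }
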