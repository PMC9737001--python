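"""Calibrate the baseline hospital and characterise its congestion regime.

Searches the global arrival-intensity multiplier by bisection so that the
baseline (scenario 0) produces a 10 AM inpatient census of 320-335 beds and
50-160 congestion episodes in the collection year, then reports the baseline
operating point at the committed default (multiplier 1.0, per-unit offered
load 0.88 before the day-shift discharge rhythm).

Writes results/calibration.json.
"""

import json
from pathlib import Path

from hospitalflow import default_config
from hospitalflow.experiment import (
    ExperimentPlan,
    aggregate_replications,
    calibrate_arrival_multiplier,
    run_scenario_replications,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    search = calibrate_arrival_multiplier(target_events=110.0, replications=3,
                                          base_seed=1)
    print("bisection trace (multiplier -> baseline events/year):")
    for m, e in search["trace"]:
        print(f"  {m:.4f} -> {e:.1f}")
    print(f"chosen multiplier: {search['multiplier']:.4f} "
          f"({search['events']:.1f} events/year, in band: {search['in_band']})")

    plan = ExperimentPlan(scenario_ids=(0,), replications=5, base_seed=1)
    agg = aggregate_replications(
        run_scenario_replications(default_config(), 0, plan))
    print(f"\nbaseline at committed defaults (5 reps x 2 years, year 2 collected):")
    print(f"  mean 10 AM occupancy: {agg.mean_occupancy_10am:.1f} beds "
          f"(band 320-335)")
    print(f"  congestion events/year: {agg.n_congestion_events:.1f} (band 50-160)")
    print(f"  episode duration mean/max: {agg.mean_congestion_h:.1f} / "
          f"{agg.max_congestion_h:.1f} h")

    with open(OUT / "calibration.json", "w") as fh:
        json.dump({
            "search": {"multiplier": search["multiplier"],
                       "events": search["events"],
                       "trace": search["trace"]},
            "baseline": {
                "mean_occupancy_10am": agg.mean_occupancy_10am,
                "occupancy_std": agg.occupancy_std,
                "n_congestion_events": agg.n_congestion_events,
                "mean_congestion_h": agg.mean_congestion_h,
                "max_congestion_h": agg.max_congestion_h,
            },
        }, fh, indent=2)
    print(f"\nwrote {OUT / 'calibration.json'}")


if __name__ == "__main__":
    main()
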