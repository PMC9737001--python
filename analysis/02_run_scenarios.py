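"""Run all 27 decongestion scenarios on the synthetic hospital.

Each scenario runs 5 replications of 2 simulated years with common random
numbers (replication r of every scenario shares seed 1+r); the first year is
warm-up, the second is collected.  Writes the scenario results table
(results/results.csv) plus a provenance record sufficient to regenerate it.
"""

from pathlib import Path

from hospitalflow.experiment import ExperimentPlan, run_experiment

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    plan = ExperimentPlan(scenario_ids=tuple(range(27)), replications=5,
                          years=2, base_seed=1, output_dir=str(OUT))
    df = run_experiment(plan)
    print(df.to_string(float_format=lambda v: f"{v:.3f}"))

    base = df.loc[0, "n_congestion_events"]
    better = df.index[df["n_congestion_events"] < base].tolist()
    worse = df.index[df["n_congestion_events"] > base].tolist()
    print(f"\nbaseline: {base:.1f} events/year")
    print(f"scenarios reducing congestion events: {sorted(set(better) - {0})}")
    print(f"scenarios increasing congestion events: {sorted(set(worse) - {0})}")
    print(f"wrote {OUT / 'results.csv'} and {OUT / 'provenance.json'}")


if __name__ == "__main__":
    main()
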