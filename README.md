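# hospitalflow

Discrete-event simulation of whole-hospital patient flow and a comparison of
27 congestion-triggered decongestion scenarios.

The model covers a medium-sized acute hospital: an emergency department (ED)
with 18 admission beds, a 24-bed acute medical unit (AMU), a 170-bed medical
ward group and a 143-bed surgical ward group (337 inpatient beds in total).
Emergency patients arrive by ambulance or walk-in on a week-periodic
time-varying Poisson process; elective surgical patients arrive on weekday
mornings. Admitted patients who cannot get a ward bed board in the ED
("access block"), which is the mechanism that couples ward crowding back to
ED crowding.

The hospital is *congested* at an hourly check when all three of the
following hold: at least 17 ED admission beds occupied, inpatient occupancy
at or above 97 %, and at least 28 patients waiting in the ED. Maximal runs of
congested checks form *congestion episodes*. One hour after an episode
starts — if it is still in progress — a scenario-specific action can fire:

| ids   | action |
|-------|--------|
| 0     | baseline, no action |
| 1–3   | add 2 / 4 / 6 ED admission beds |
| 4–6   | add 2 / 4 / 6 AMU beds |
| 7–9   | move 2 / 4 / 6 surgical beds to medical |
| 10–12 | move 2 / 4 / 6 medical beds to surgical |
| 13–15 | transfer 2 / 4 / 6 ED boarders to another facility |
| 16–18 | discharge 2 / 4 / 6 low-acuity inpatients early |
| 19–21 | postpone 2 / 4 / 6 elective operations (FIFO backlog) |
| 22–23 | divert 2 / 4 ambulances per episode |
| 24–25 | transfer 1 + divert 1 / transfer 2 + divert 2 |
| 26    | transfer 1 + divert 1 + discharge 1 medical + 1 surgical |

Patient-level actions are compared by a per-patient *efficiency* statistic:
the reduction in congestion events (or mean episode duration) divided by the
number of patients affected, diverted or postponed.

## Quick start

```python
from hospitalflow import default_config, run_simulation, summarize_run

cfg = default_config()
traj = run_simulation(cfg, scenario=22, years=2, seed=1)
m = summarize_run(traj, window=(8760, 17520))   # collect year 2
print(m.n_congestion_events, m.mean_congestion_h)
```

or from the command line:

```
hospitalflow simulate --scenario 0 --scenario 22 --reps 5 --seed 1 --out results/
hospitalflow report --results results/results.csv --rank events
```

## Analysis pipeline

Numbered scripts under `analysis/` reproduce the study end to end
(roughly two minutes total):

1. `analysis/01_calibrate_baseline.py` — bisects a global arrival-intensity
   multiplier so the baseline produces a plausible crisis rate, and reports
   the committed default. At the defaults the baseline (5 replications ×
   2 years, year 2 collected) gives a mean 10 AM inpatient census of
   **327.4 beds** and **109.8 congestion events per year** with mean episode
   duration 17.4 h.
2. `analysis/02_run_scenarios.py` — runs all 27 scenarios with common random
   numbers (5 replications × 2 years) and writes `results/results.csv` plus
   a `provenance.json` with the configuration hash and seeds. At seed 1,
   every extra-capacity, transfer, early-discharge and diversion scenario
   reduces congestion events below baseline, while moving medical beds to
   surgical (10–12) and postponing electives (19–21) increase them.
3. `analysis/03_efficiency_ranking.py` — ranks scenarios and writes
   `results/efficiency.csv`. Transfers of ED boarders (13–15) are the most
   event-efficient per affected patient (0.28–0.31 events/patient), followed
   by the combined transfer+divert scenarios.

## Tests

```
python -m pytest -q
```

150 tests (about 40 s): unit tests per module, hypothesis property tests for
the episode segmentation, and an end-to-end acceptance suite covering exact
efficiency reconstruction, patient conservation under all 27 scenarios, the
baseline calibration band and directional scenario responses.

## Layout

- `src/hospitalflow/` — the library (configuration, arrival synthesis,
  simulation engine, congestion detection, scenarios, metrics, experiment
  driver, CLI, reference summaries).
- `analysis/` — numbered scripts producing `results/`.
- `docs/methods.md` — model description, parameter rationale, numerical
  choices and known limitations.
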