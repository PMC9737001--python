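import numpy as np
import pytest

from hospitalflow import (
    BedUnit,
    Patient,
    default_config,
    request_bed,
    run_simulation,
    snapshot_10am_occupancy,
)
from hospitalflow.engine import TrajectoryRecord


# ------------------------------------------------------------- BedUnit
def test_bed_request_seated_then_queued():
    unit = BedUnit("amu", capacity=1)
    assert request_bed(unit, Patient(1, 3, "walk_in")) == "seated"
    assert request_bed(unit, Patient(2, 3, "walk_in"), time=1.0) == "queued"


def test_double_allocation_rejected():
    unit = BedUnit("ed", capacity=2)
    p = Patient(1, 3, "walk_in")
    unit.request(p)
    with pytest.raises(ValueError, match="already holds"):
        unit.request(p)


def test_queue_serves_most_urgent_triage_first():
    unit = BedUnit("ed", capacity=1)
    unit.request(Patient(0, 3, "walk_in"), time=0.0)
    unit.request(Patient(1, 4, "walk_in"), time=1.0)  # arrived first, less urgent
    unit.request(Patient(2, 2, "ambulance"), time=2.0)
    nxt = unit.release(0)
    assert nxt.id == 2  # triage 2 overtakes triage 4


def test_queue_fcfs_within_triage_class():
    unit = BedUnit("ed", capacity=1)
    unit.request(Patient(0, 3, "walk_in"), time=0.0)
    unit.request(Patient(1, 3, "walk_in"), time=1.0)
    unit.request(Patient(2, 3, "walk_in"), time=2.0)
    assert unit.release(0).id == 1


def test_zero_capacity_unit_rejected():
    with pytest.raises(ValueError):
        BedUnit("ed", 0)


# ------------------------------------------------------------- run_simulation
def test_empty_system_stays_empty(quiet_cfg):
    traj = run_simulation(quiet_cfg, 0, hours=48, seed=0)
    assert traj.ed_occupied.sum() == 0
    assert traj.ed_queue_len.sum() == 0
    assert traj.inpatient_occupied.sum() == 0
    assert traj.n_patients == 0


def test_single_walk_in_hand_trace(trace_cfg):
    """One walk-in at t=5.5 h, 3 h treatment, not admitted.

    Discharge milestone lands at arrival + 3 h and the ED bed shows
    occupied on exactly the three hourly checks 6, 7 and 8.
    """
    arrivals = {"time": np.array([5.5]), "mode": np.array([1]),
                "triage": np.array([3])}
    traj = run_simulation(trace_cfg, 0, hours=24, seed=0,
                          arrivals=arrivals, log_events=True)
    events = {e: t for _, e, t, _ in traj.event_log}
    assert events["arrival"] == 5.5
    assert events["ed_bed_start"] == 5.5
    assert events["discharge"] == pytest.approx(8.5)
    assert traj.ed_occupied.tolist() == [0] * 6 + [1, 1, 1] + [0] * 15
    assert traj.disposition_counts() == {"completed": 1}


def test_milestones_nondecreasing_along_pathway(cfg):
    traj = run_simulation(cfg, 0, hours=24 * 21, seed=3, log_events=True)
    order = {"arrival": 0, "ed_bed_start": 1, "admit_request": 2,
             "ward_bed_start": 3, "discharge": 4}
    per_patient = {}
    for pid, event, t, _ in traj.event_log:
        if event in order:
            per_patient.setdefault(pid, []).append((order[event], t))
    for seqs in per_patient.values():
        times = [t for _, t in sorted(seqs)]
        assert times == sorted(times)


def test_identical_seed_gives_identical_event_logs(cfg):
    a = run_simulation(cfg, 0, hours=24 * 30, seed=9, log_events=True)
    b = run_simulation(cfg, 0, hours=24 * 30, seed=9, log_events=True)
    assert a.event_log == b.event_log
    np.testing.assert_array_equal(a.ed_queue_len, b.ed_queue_len)


def test_occupancy_never_exceeds_capacity(cfg):
    for sid in (0, 3, 9, 22):
        traj = run_simulation(cfg, sid, hours=24 * 60, seed=2)
        assert traj.ed_occupied.max() <= traj.ed_capacity
        assert traj.inpatient_occupied.max() <= traj.inpatient_capacity
        assert traj.inpatient_occupancy.max() <= 1.0


def test_every_patient_reaches_exactly_one_disposition(cfg):
    traj = run_simulation(cfg, 21, hours=24 * 90, seed=5)
    counts = traj.disposition_counts()
    assert sum(counts.values()) == traj.n_patients
    present = counts.get("in_system", 0) + counts.get("postponed", 0)
    assert present == traj.in_system_structural


def test_invalid_horizon_rejected(cfg):
    with pytest.raises(ValueError):
        run_simulation(cfg, 0, years=0)
    with pytest.raises(ValueError):
        run_simulation(cfg, 0, hours=-1)


def test_infeasible_config_flags_queue_divergence():
    cfg = default_config()
    cfg.ed_admission_beds = 2
    traj = run_simulation(cfg, 0, hours=2000, seed=1)
    assert any("queue-divergence" in w for w in traj.warnings)


# ------------------------------------------------- snapshot_10am_occupancy
def _record_with_occupancy(values):
    h = len(values)
    z = np.zeros(h, dtype=np.int32)
    return TrajectoryRecord(
        horizon=h, ed_capacity=18, inpatient_capacity=337,
        time_h=np.arange(h), ed_occupied=z, ed_queue_len=z,
        inpatient_occupied=np.asarray(values, dtype=np.int32),
        episodes=[], interventions=[], divert_times=np.array([]),
        postpone_times=np.array([]), dispositions=np.array([], dtype=np.int8),
        arrival_times=np.array([]), arrival_modes=np.array([]),
        arrival_triage=np.array([]), n_patients=0, in_system_structural=0,
        warnings=[], scenario_id=0, seed=0)


def test_constant_occupancy_gives_zero_std():
    traj = _record_with_occupancy([327] * 48)
    assert snapshot_10am_occupancy(traj, (0, 48)) == (327.0, 0.0)


def test_two_day_population_std():
    vals = np.zeros(48, dtype=int)
    vals[10], vals[34] = 320, 330  # the two 10 AM checks
    traj = _record_with_occupancy(vals)
    assert snapshot_10am_occupancy(traj, (0, 48)) == (325.0, 5.0)


def test_empty_window_rejected():
    traj = _record_with_occupancy([327] * 48)
    with pytest.raises(ValueError):
        snapshot_10am_occupancy(traj, (0, 0))
    with pytest.raises(ValueError):
        snapshot_10am_occupancy(traj, (0, 100))
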