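"""Discrete-event engine for whole-hospital patient flow.

Patients move through ED queue -> ED treatment -> (discharge | inpatient
admission) with admitted medical patients passing through the AMU when a bed
is free, and surgical beds shared between emergency and elective cases.
Admitted patients who cannot get a ward bed board in their ED treatment
space, so ward saturation propagates back into the ED — the access-block
mechanism that drives congestion.

The engine is a continuous-time event queue (heapq kernel) with state
snapshots on integer hours.  Congestion is evaluated at every hourly check;
when a congestion episode begins, scenario actions are activated one hour
later, provided the episode is still in progress at that check.

Two surfaces are provided: :class:`BedUnit`/:class:`Patient` are the
object-level primitives that define bed-allocation semantics (used directly
in small compositions and tests), while :func:`run_simulation` is an
array-based implementation of the same rules optimised for multi-year runs.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import HospitalConfig
from .congestion import CongestionEpisode, CongestionThresholds
from .scenarios import ScenarioConfig, build_scenario
from .synthetic import sample_arrival_arrays

HOURS_PER_YEAR = 8760

# Disposition codes
IN_SYSTEM = 0
COMPLETED = 1
DISCHARGED_EARLY = 2
TRANSFERRED_OUT = 3
DIVERTED = 4
POSTPONED = 5

DISPOSITION_NAMES = {
    IN_SYSTEM: "in_system",
    COMPLETED: "completed",
    DISCHARGED_EARLY: "discharged",
    TRANSFERRED_OUT: "transferred_out",
    DIVERTED: "diverted",
    POSTPONED: "postponed",
}

# Patient-class codes
MEDICAL = 0
SURGICAL = 1
ELECTIVE = 2

# Ward discharges are processed during the day shift; a stay ending
# overnight completes at the next morning's discharge round.  This is the
# intra-day rhythm that concentrates peak occupancy in the late morning and
# lets congestion episodes resolve when the afternoon discharges land.
_DISCHARGE_OPEN = 11.0
_DISCHARGE_CLOSE = 19.0


def _align_discharge(t: float) -> float:
    """Defer an inpatient discharge falling outside the day shift.

    Deterministic in ``t``: the fractional hour spreads deferred discharges
    over the 11:00-15:00 midday round, preserving common random numbers.
    """
    hod = t % 24.0
    if _DISCHARGE_OPEN <= hod < _DISCHARGE_CLOSE:
        return t
    offset = _DISCHARGE_OPEN + (t % 1.0) * 4.0
    if hod < _DISCHARGE_OPEN:
        return t - hod + offset
    return t - hod + 24.0 + offset


# ----------------------------------------------------------------------
# Object-level primitives
# ----------------------------------------------------------------------
@dataclass
class Patient:
    """A patient agent with journey-milestone tracking."""

    id: int
    triage: int
    mode: str  # ambulance | walk_in | elective
    patient_class: str = ""  # medical | surgical
    milestones: dict = field(default_factory=dict)
    disposition: str = "in_system"

    def record(self, event: str, time: float) -> None:
        self.milestones[event] = time


class BedUnit:
    """A capacitated bed pool with a priority waiting queue.

    Waiting patients are served lowest triage score first (most urgent),
    ties broken by arrival time — first-come-first-served within a triage
    class.
    """

    def __init__(self, name: str, capacity: int):
        if capacity <= 0:
            raise ValueError(f"{name}: capacity must be positive")
        self.name = name
        self.capacity = capacity
        self.occupants: set = set()
        self._queue: list = []
        self._seq = 0

    @property
    def occupied(self) -> int:
        return len(self.occupants)

    def request(self, patient: Patient, time: float = 0.0) -> str:
        """Seat the patient if a bed is free, otherwise queue them.

        Returns ``"seated"`` or ``"queued"``.  A patient already holding a
        bed in this unit cannot request another.
        """
        if patient.id in self.occupants:
            raise ValueError(
                f"patient {patient.id} already holds a bed in {self.name}"
            )
        if self.occupied < self.capacity:
            self.occupants.add(patient.id)
            return "seated"
        heapq.heappush(self._queue, (patient.triage, time, self._seq, patient))
        self._seq += 1
        return "queued"

    def release(self, patient_id: int):
        """Free a bed; seat and return the next waiting patient, if any."""
        self.occupants.discard(patient_id)
        if self._queue and self.occupied < self.capacity:
            _, _, _, nxt = heapq.heappop(self._queue)
            self.occupants.add(nxt.id)
            return nxt
        return None

    @property
    def queue_length(self) -> int:
        return len(self._queue)


def request_bed(unit: BedUnit, patient: Patient, time: float = 0.0) -> str:
    """Request a bed in ``unit`` for ``patient`` (seated or queued)."""
    return unit.request(patient, time)


# ----------------------------------------------------------------------
# Trajectory record
# ----------------------------------------------------------------------
@dataclass
class TrajectoryRecord:
    """Output of one simulation run.

    Hourly snapshot arrays are indexed by hour 0..horizon-1; the event log is
    populated only when the run was started with ``log_events=True``.
    """

    horizon: int
    ed_capacity: int
    inpatient_capacity: int
    time_h: np.ndarray
    ed_occupied: np.ndarray
    ed_queue_len: np.ndarray
    inpatient_occupied: np.ndarray
    episodes: list
    interventions: list  # dicts: time, episode_start, action, pids, requested, actual
    divert_times: np.ndarray
    postpone_times: np.ndarray
    dispositions: np.ndarray
    arrival_times: np.ndarray
    arrival_modes: np.ndarray
    arrival_triage: np.ndarray
    n_patients: int
    in_system_structural: int
    warnings: list
    scenario_id: int
    seed: int
    event_log: list | None = None

    @property
    def inpatient_occupancy(self) -> np.ndarray:
        """Occupancy fraction of inpatient capacity per hourly snapshot."""
        return self.inpatient_occupied / self.inpatient_capacity

    def disposition_counts(self) -> dict:
        vals, counts = np.unique(self.dispositions, return_counts=True)
        return {DISPOSITION_NAMES[int(v)]: int(c) for v, c in zip(vals, counts)}

    def snapshots_to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_h", "ed_occupied", "ed_queue_len", "inpatient_occupancy"])
            occ = self.inpatient_occupancy
            for i in range(self.horizon):
                w.writerow([i, int(self.ed_occupied[i]), int(self.ed_queue_len[i]),
                            f"{occ[i]:.6f}"])

    def event_log_to_jsonl(self, path) -> None:
        import json

        if self.event_log is None:
            raise ValueError("run was executed without log_events=True")
        with open(path, "w") as fh:
            for pid, event, t, unit in self.event_log:
                fh.write(json.dumps(
                    {"patient_id": int(pid), "event": event,
                     "time_h": round(float(t), 6), "unit": unit}) + "\n")


def snapshot_10am_occupancy(
    trajectory: TrajectoryRecord, window: tuple[int, int]
) -> tuple[float, float]:
    """Mean and population std-dev of 10 AM inpatient occupancy (in beds).

    ``window`` is a half-open hour interval [start, end) within the horizon.
    """
    start, end = window
    if not (0 <= start < end <= trajectory.horizon):
        raise ValueError(f"window {window} outside horizon {trajectory.horizon}")
    hours = np.arange(start, end)
    sel = hours[hours % 24 == 10]
    if sel.size == 0:
        raise ValueError("window contains no 10 AM snapshot")
    vals = trajectory.inpatient_occupied[sel].astype(float)
    return float(vals.mean()), float(vals.std())  # population std-dev


# ----------------------------------------------------------------------
# Main simulation
# ----------------------------------------------------------------------
def run_simulation(
    config: HospitalConfig,
    scenario: ScenarioConfig | int | None = None,
    years: int = 1,
    seed: int = 0,
    thresholds: CongestionThresholds | None = None,
    hours: float | None = None,
    log_events: bool = False,
    arrivals: dict | None = None,
) -> TrajectoryRecord:
    """Simulate ``years`` of hospital operation under one scenario.

    Deterministic given (config, scenario, seed): identical inputs produce
    identical trajectories and event logs.  ``hours`` overrides ``years``
    for reduced-scale runs.  ``arrivals`` injects a pre-built arrival stream
    (dict with ``time``, ``mode``, ``triage`` arrays as produced by
    :func:`hospitalflow.synthetic.sample_arrival_arrays`) in place of
    sampling one — useful for hand-traced event sequences.

    Infeasible configurations (queues growing without bound) complete but
    set a queue-divergence warning on the returned record.
    """
    if scenario is None:
        scenario = build_scenario(0)
    elif isinstance(scenario, int):
        scenario = build_scenario(scenario)
    if thresholds is None:
        thresholds = CongestionThresholds()
    if hours is None:
        if years < 1:
            raise ValueError("years must be >= 1 (use hours= for shorter runs)")
        H = int(years) * HOURS_PER_YEAR
    else:
        if hours <= 0:
            raise ValueError("hours must be positive")
        H = int(hours)

    ed_cap = config.ed_admission_beds + scenario.delta("ed")
    amu_cap = config.amu_beds + scenario.delta("amu")
    med_cap = config.medical_beds + scenario.delta("medical")
    surg_cap = config.surgical_beds + scenario.delta("surgical")
    for name, cap in (("ed", ed_cap), ("amu", amu_cap),
                      ("medical", med_cap), ("surgical", surg_cap)):
        if cap <= 0:
            raise ValueError(f"scenario {scenario.id} drives {name} capacity to {cap}")
    inpat_cap = amu_cap + med_cap + surg_cap

    # ---- input streams and per-patient stochastic attributes -----------
    rng = np.random.default_rng(seed)
    arr = arrivals if arrivals is not None else sample_arrival_arrays(config, H, rng)
    t_arr = np.asarray(arr["time"], dtype=float)
    mode_arr = np.asarray(arr["mode"], dtype=np.int8)  # 0 amb, 1 walk, 2 elective
    triage_arr = np.asarray(arr["triage"], dtype=np.int64)
    n = t_arr.size

    admit_p = config.admit_probability[triage_arr - 1]
    is_ed = mode_arr != 2
    admitted = (rng.random(n) < admit_p) & is_ed
    is_medical = admitted & (rng.random(n) < config.class_split)

    cls = np.where(mode_arr == 2, ELECTIVE, np.where(is_medical, MEDICAL, SURGICAL))
    mu, sg = config.ed_treatment_params
    ed_los = rng.lognormal(mu, sg, n)
    mu, sg = config.los_params["amu"]
    amu_los = rng.lognormal(mu, sg, n)
    draws = {
        c: rng.lognormal(*config.los_params[c], n)
        for c in ("medical", "surgical", "elective_surgical")
    }
    ward_los = np.select(
        [cls == MEDICAL, cls == SURGICAL, cls == ELECTIVE],
        [draws["medical"], draws["surgical"], draws["elective_surgical"]],
    )

    # ---- state ----------------------------------------------------------
    disposition = np.zeros(n, dtype=np.int8)
    ed_occ = 0  # treating + boarding patients holding ED beds
    ed_treating = 0
    amu_occ = med_occ = surg_occ = 0
    ed_queue: list = []  # (triage, time, pid)
    med_ed_wait: deque = deque()  # admitted medical patients boarding in ED
    surg_ed_wait: deque = deque()  # admitted surgical patients boarding in ED
    amu_block: deque = deque()  # AMU-complete patients awaiting a medical bed
    elective_wait: deque = deque()
    backlog: deque = deque()
    wait_start: dict = {}
    in_amu: dict = {}  # pid -> scheduled AMU completion (assessment phase)
    in_med: dict = {}  # pid -> scheduled ward discharge
    in_surg: dict = {}

    heap: list = []
    seq = 0
    ED_DONE, AMU_DONE, MED_DONE, SURG_DONE, ACTIVATE = 0, 1, 2, 3, 4

    in_episode = False
    activated = False
    ep_start = -1
    divert_quota = 0
    postpone_intercept = 0
    episodes: list = []
    interventions: list = []
    divert_times: list = []
    postpone_times: list = []

    snap_ed = np.zeros(H, dtype=np.int32)
    snap_q = np.zeros(H, dtype=np.int32)
    snap_in = np.zeros(H, dtype=np.int32)

    log = [] if log_events else None

    def emit(pid, event, t, unit=""):
        if log is not None:
            log.append((pid, event, t, unit))

    def push(t, kind, pid):
        nonlocal seq
        heapq.heappush(heap, (t, seq, kind, pid))
        seq += 1

    # ---- bed-release cascades -------------------------------------------
    def free_ed_bed(t):
        nonlocal ed_occ, ed_treating
        ed_occ -= 1
        if ed_queue and ed_occ < ed_cap:
            _, _, pid = heapq.heappop(ed_queue)
            ed_occ += 1
            ed_treating += 1
            emit(pid, "ed_bed_start", t, "ed")
            push(t + ed_los[pid], ED_DONE, pid)

    def free_amu_bed(t):
        # a patient has vacated an AMU bed (amu_occ already decremented)
        nonlocal amu_occ
        if med_ed_wait:
            pid = med_ed_wait.popleft()
            wait_start.pop(pid, None)
            amu_occ += 1
            in_amu[pid] = t + amu_los[pid]
            emit(pid, "ward_bed_start", t, "amu")
            push(in_amu[pid], AMU_DONE, pid)
            free_ed_bed(t)

    def free_medical_bed(t):
        nonlocal med_occ, amu_occ
        if amu_block:
            pid = amu_block.popleft()
            wait_start.pop(pid, None)
            med_occ += 1
            in_med[pid] = _align_discharge(t + ward_los[pid])
            emit(pid, "ward_bed_start", t, "medical")
            push(in_med[pid], MED_DONE, pid)
            amu_occ -= 1
            free_amu_bed(t)
        elif med_ed_wait:
            pid = med_ed_wait.popleft()
            wait_start.pop(pid, None)
            med_occ += 1
            # assessment happens on the ward when the AMU was bypassed
            in_med[pid] = _align_discharge(t + amu_los[pid] + ward_los[pid])
            emit(pid, "ward_bed_start", t, "medical")
            push(in_med[pid], MED_DONE, pid)
            free_ed_bed(t)

    def admit_surgical(pid, t, from_backlog=False):
        nonlocal surg_occ
        surg_occ += 1
        in_surg[pid] = _align_discharge(t + ward_los[pid])
        emit(pid, "ward_bed_start", t, "surgical")
        push(in_surg[pid], SURG_DONE, pid)
        if from_backlog:
            disposition[pid] = IN_SYSTEM
            emit(pid, "backlog_admit", t, "surgical")

    def free_surgical_bed(t):
        nonlocal surg_occ
        if surg_ed_wait:
            pid = surg_ed_wait.popleft()
            wait_start.pop(pid, None)
            admit_surgical(pid, t)
            free_ed_bed(t)
        elif backlog and not in_episode:
            admit_surgical(backlog.popleft(), t, from_backlog=True)
        elif elective_wait:
            admit_surgical(elective_wait.popleft(), t)

    def drain_backlog(t):
        while backlog and not in_episode and surg_occ < surg_cap:
            admit_surgical(backlog.popleft(), t, from_backlog=True)

    # ---- scenario activation --------------------------------------------
    def do_activation(t):
        nonlocal activated, divert_quota, postpone_intercept
        nonlocal med_ed_wait, surg_ed_wait
        activated = True
        rec = {"time": t, "episode_start": ep_start}
        # transfers: admitted ED boarders, least urgent first, longest-boarding
        # first within a triage score
        if scenario.transfer_ed_n:
            cands = [(int(triage_arr[p]), wait_start.get(p, t), p)
                     for p in list(med_ed_wait) + list(surg_ed_wait)]
            cands.sort(key=lambda c: (-c[0], c[1]))
            chosen = [p for _, _, p in cands[: scenario.transfer_ed_n]]
            if chosen:
                chosen_set = set(chosen)
                med_ed_wait = deque(p for p in med_ed_wait if p not in chosen_set)
                surg_ed_wait = deque(p for p in surg_ed_wait if p not in chosen_set)
                for p in chosen:
                    wait_start.pop(p, None)
                    disposition[p] = TRANSFERRED_OUT
                    emit(p, "transfer", t, "ed")
                    free_ed_bed(t)
            rec["transfer"] = {"requested": scenario.transfer_ed_n,
                               "actual": len(chosen), "pids": chosen}
        # early discharges: triage >= 4, nearest to scheduled discharge first
        if scenario.discharge_inpatient_n:
            def pool(units):
                out = []
                for unit, table in units:
                    for p, t_done in table.items():
                        if triage_arr[p] >= 4:
                            out.append((t_done, p, unit))
                out.sort()
                return out

            if scenario.discharge_per_class:
                picks = []
                for pcls, k in scenario.discharge_per_class:
                    units = ([("surgical", in_surg)] if pcls == "surgical"
                             else [("amu", in_amu), ("medical", in_med)])
                    picks.extend(pool(units)[:k])
            else:
                picks = pool([("amu", in_amu), ("medical", in_med),
                              ("surgical", in_surg)])[: scenario.discharge_inpatient_n]
            for _, p, unit in picks:
                disposition[p] = DISCHARGED_EARLY
                emit(p, "discharge", t, unit)
                _early_release(p, unit, t)
            rec["discharge"] = {"requested": scenario.discharge_inpatient_n,
                                "actual": len(picks), "pids": [p for _, p, _ in picks]}
        # postponements: waiting electives first, then intercept upcoming
        # elective arrivals while the episode lasts
        if scenario.postpone_elective_n:
            moved = []
            while elective_wait and len(moved) < scenario.postpone_elective_n:
                p = elective_wait.popleft()
                backlog.append(p)
                disposition[p] = POSTPONED
                postpone_times.append(t)
                emit(p, "postpone", t, "surgical")
                moved.append(p)
            postpone_intercept = scenario.postpone_elective_n - len(moved)
            rec["postpone"] = {"requested": scenario.postpone_elective_n,
                               "actual": len(moved), "pids": moved}
        if scenario.divert_ambulance_n:
            divert_quota = scenario.divert_ambulance_n
            rec["divert_quota"] = scenario.divert_ambulance_n
        interventions.append(rec)

    def _early_release(pid, unit, t):
        nonlocal amu_occ, med_occ, surg_occ
        if unit == "amu":
            del in_amu[pid]
            amu_occ -= 1
            free_amu_bed(t)
        elif unit == "medical":
            del in_med[pid]
            med_occ -= 1
            free_medical_bed(t)
        else:
            del in_surg[pid]
            surg_occ -= 1
            free_surgical_bed(t)

    # ---- main loop -------------------------------------------------------
    i = 0  # arrival pointer
    next_check = 0
    INF = float("inf")
    while True:
        ta = t_arr[i] if i < n else INF
        th = heap[0][0] if heap else INF
        tc = float(next_check) if next_check < H else INF
        tmin = min(ta, th, tc)
        if tmin == INF or tmin >= H:
            break

        if tc <= ta and tc <= th:
            # ---- hourly congestion check / snapshot ----
            q = len(ed_queue)
            occ = amu_occ + med_occ + surg_occ
            snap_ed[next_check] = ed_occ
            snap_q[next_check] = q
            snap_in[next_check] = occ
            flag = (
                ed_occ >= thresholds.ed_min_occupied
                and occ >= thresholds.inpatient_min_occupancy * inpat_cap
                and q >= thresholds.queue_min
            ) if thresholds.conjunctive else (
                ed_occ >= thresholds.ed_min_occupied
                or occ >= thresholds.inpatient_min_occupancy * inpat_cap
                or q >= thresholds.queue_min
            )
            if flag and not in_episode:
                in_episode = True
                ep_start = next_check
                if scenario.has_patient_actions:
                    push(float(next_check + 1), ACTIVATE, -1)
            elif not flag and in_episode:
                episodes.append(CongestionEpisode(ep_start, next_check))
                in_episode = False
                activated = False
                divert_quota = 0
                postpone_intercept = 0
                drain_backlog(float(next_check))
            next_check += 1
            continue

        if th <= ta:
            t, _, kind, pid = heapq.heappop(heap)
            if kind == ED_DONE:
                ed_treating -= 1
                if not admitted[pid]:
                    disposition[pid] = COMPLETED
                    emit(pid, "discharge", t, "ed")
                    free_ed_bed(t)
                else:
                    emit(pid, "admit_request", t, "ed")
                    if cls[pid] == MEDICAL:
                        if amu_occ < amu_cap:
                            amu_occ += 1
                            in_amu[pid] = t + amu_los[pid]
                            emit(pid, "ward_bed_start", t, "amu")
                            push(in_amu[pid], AMU_DONE, pid)
                            free_ed_bed(t)
                        elif med_occ < med_cap:
                            med_occ += 1
                            in_med[pid] = _align_discharge(t + amu_los[pid] + ward_los[pid])
                            emit(pid, "ward_bed_start", t, "medical")
                            push(in_med[pid], MED_DONE, pid)
                            free_ed_bed(t)
                        else:
                            med_ed_wait.append(pid)
                            wait_start[pid] = t
                    else:
                        if surg_occ < surg_cap:
                            admit_surgical(pid, t)
                            free_ed_bed(t)
                        else:
                            surg_ed_wait.append(pid)
                            wait_start[pid] = t
            elif kind == AMU_DONE:
                if pid in in_amu:
                    del in_amu[pid]
                    if med_occ < med_cap:
                        med_occ += 1
                        in_med[pid] = _align_discharge(t + ward_los[pid])
                        emit(pid, "ward_bed_start", t, "medical")
                        push(in_med[pid], MED_DONE, pid)
                        amu_occ -= 1
                        free_amu_bed(t)
                    else:
                        amu_block.append(pid)
                        wait_start[pid] = t
            elif kind == MED_DONE:
                if pid in in_med:
                    del in_med[pid]
                    disposition[pid] = COMPLETED
                    emit(pid, "discharge", t, "medical")
                    med_occ -= 1
                    free_medical_bed(t)
            elif kind == SURG_DONE:
                if pid in in_surg:
                    del in_surg[pid]
                    disposition[pid] = COMPLETED
                    emit(pid, "discharge", t, "surgical")
                    surg_occ -= 1
                    free_surgical_bed(t)
            else:  # ACTIVATE
                if in_episode and ep_start == int(t) - 1:
                    do_activation(t)
            continue

        # ---- arrival ----
        t = ta
        pid = i
        i += 1
        m = mode_arr[pid]
        if m == 2:  # elective
            emit(pid, "arrival", t, "elective")
            drain_backlog(t)
            if activated and in_episode and postpone_intercept > 0:
                postpone_intercept -= 1
                backlog.append(pid)
                disposition[pid] = POSTPONED
                postpone_times.append(t)
                emit(pid, "postpone", t, "surgical")
            elif surg_occ < surg_cap:
                admit_surgical(pid, t)
            else:
                elective_wait.append(pid)
        else:
            if m == 0 and activated and in_episode and divert_quota > 0:
                divert_quota -= 1
                disposition[pid] = DIVERTED
                divert_times.append(t)
                emit(pid, "divert", t, "ed")
                continue
            emit(pid, "arrival", t, "ed")
            if ed_occ < ed_cap:
                ed_occ += 1
                ed_treating += 1
                emit(pid, "ed_bed_start", t, "ed")
                push(t + ed_los[pid], ED_DONE, pid)
            else:
                heapq.heappush(ed_queue, (int(triage_arr[pid]), t, pid))

    if in_episode:
        episodes.append(CongestionEpisode(ep_start, H))

    in_system_structural = (
        len(ed_queue) + ed_occ + amu_occ + med_occ + surg_occ
        + len(elective_wait) + len(backlog)
    )

    warnings = []
    # Divergence check: a sustained linear growth of the ED queue over the
    # run indicates an infeasible configuration rather than transient
    # congestion crises.
    if H >= 48:
        k = max(24, H // 10)
        growth = float(snap_q[-k:].mean() - snap_q[:k].mean())
        if growth > max(100.0, 0.05 * H):
            warnings.append(
                f"queue-divergence: ED queue grew by ~{growth:.0f} patients "
                "over the run; configuration may be infeasible"
            )

    return TrajectoryRecord(
        horizon=H,
        ed_capacity=ed_cap,
        inpatient_capacity=inpat_cap,
        time_h=np.arange(H),
        ed_occupied=snap_ed,
        ed_queue_len=snap_q,
        inpatient_occupied=snap_in,
        episodes=episodes,
        interventions=interventions,
        divert_times=np.array(divert_times),
        postpone_times=np.array(postpone_times),
        dispositions=disposition,
        arrival_times=t_arr,
        arrival_modes=mode_arr,
        arrival_triage=triage_arr,
        n_patients=n,
        in_system_structural=in_system_structural,
        warnings=warnings,
        scenario_id=scenario.id,
        seed=seed,
        event_log=log,
    )
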