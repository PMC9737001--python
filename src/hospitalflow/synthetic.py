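"""Stochastic input processes for the synthetic hospital.

Arrivals follow time-varying Poisson processes on a week-periodic
hour-of-day x day-of-week intensity grid, one independent process per stream
(ambulance, walk-in, elective).  Lengths of stay are log-normal per patient
class — the canonical right-skewed family for hospital stays.

All sampling is driven by a caller-supplied :class:`numpy.random.Generator`,
so identical seed + config yields bit-identical streams.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .config import LOS_CLASSES, HospitalConfig


class ArrivalEvent(NamedTuple):
    """One arrival: time in hours from simulation start (Monday 00:00)."""

    time: float
    mode: str  # "ambulance" | "walk_in" | "elective"
    triage: int  # 1..5 (electives are scheduled cases, triage 5)
    patient_class: str  # "medical" | "surgical" | "" (undetermined ED arrival)


def _sample_stream_times(
    grid: np.ndarray, horizon: float, rng: np.random.Generator
) -> np.ndarray:
    """Event times of a piecewise-constant-rate Poisson process.

    The intensity is constant on each simulation hour, taken from the 7x24
    grid with week periodicity.  Sampling is exact: a Poisson count per hour
    slot, uniform placement within the slot.
    """
    n_hours = int(np.ceil(horizon))
    hours = np.arange(n_hours)
    rates = grid[(hours // 24) % 7, hours % 24]
    counts = rng.poisson(rates)
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    starts = np.repeat(hours.astype(float), counts)
    times = starts + rng.random(total)
    times.sort()
    return times[times < horizon]


def sample_arrival_arrays(
    config: HospitalConfig, horizon: float, rng: np.random.Generator
) -> dict:
    """Merged, time-ordered arrival streams as parallel numpy arrays.

    Returns a dict with keys ``time`` (float hours), ``mode`` (0 = ambulance,
    1 = walk-in, 2 = elective) and ``triage`` (1..5; electives fixed at 5).
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")

    amb = _sample_stream_times(config.arrival_rates["ambulance"], horizon, rng)
    walk = _sample_stream_times(config.arrival_rates["walk_in"], horizon, rng)
    elective = _sample_stream_times(config.arrival_rates["elective"], horizon, rng)

    n_ed = amb.size + walk.size
    triage_ed = rng.choice(5, size=n_ed, p=config.triage_pmf) + 1

    time = np.concatenate([amb, walk, elective])
    mode = np.concatenate(
        [np.zeros(amb.size, dtype=np.int8),
         np.ones(walk.size, dtype=np.int8),
         np.full(elective.size, 2, dtype=np.int8)]
    )
    # Scheduled elective cases carry the least-urgent triage score.
    triage = np.concatenate([triage_ed.astype(np.int8), np.full(elective.size, 5, np.int8)])

    order = np.argsort(time, kind="stable")
    return {"time": time[order], "mode": mode[order], "triage": triage[order]}


_MODE_NAMES = ("ambulance", "walk_in", "elective")


def sample_arrivals(
    config: HospitalConfig, horizon: float, rng: np.random.Generator
) -> list[ArrivalEvent]:
    """Time-ordered list of arrivals over ``horizon`` hours.

    ED arrivals carry a triage score drawn from the configured mix; their
    medical/surgical class is decided at admission time by the simulation,
    so ``patient_class`` is empty for them.  Elective arrivals are surgical
    by construction and occur only in the configured weekday windows.
    """
    arr = sample_arrival_arrays(config, horizon, rng)
    out = []
    for t, m, tr in zip(arr["time"], arr["mode"], arr["triage"]):
        cls = "surgical" if m == 2 else ""
        out.append(ArrivalEvent(float(t), _MODE_NAMES[m], int(tr), cls))
    return out


def sample_los(
    config: HospitalConfig, patient_class: str, rng: np.random.Generator
) -> float:
    """One log-normal stay duration in hours for the given class.

    With scale parameter sigma = 0 the draw degenerates to exp(mu) exactly.
    """
    if patient_class == "ed_treatment":
        mu, sigma = config.ed_treatment_params
    elif patient_class in config.los_params:
        mu, sigma = config.los_params[patient_class]
    else:
        raise ValueError(
            f"unknown patient class {patient_class!r}; expected one of {LOS_CLASSES}"
        )
    return float(rng.lognormal(mu, sigma))


def arrivals_to_csv(arrivals: list[ArrivalEvent], path) -> None:
    """Write an arrival stream as CSV (time_h, stream, mode, triage, class)."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_h", "stream", "mode", "triage", "class"])
        for a in arrivals:
            stream = "elective" if a.mode == "elective" else "ed"
            w.writerow([f"{a.time:.6f}", stream, a.mode, a.triage, a.patient_class])
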