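"""Catalog of the 27 decongestion scenarios.

Scenario 0 is the do-nothing baseline.  Scenarios 1-12 resize physical
units (permanent capacity changes for the whole run); scenarios 13-26 are
patient-level actions triggered one hour after a congestion episode begins:
transferring admitted ED patients to other hospitals, discharging low-acuity
inpatients early, postponing elective surgeries into a reschedule backlog,
and diverting incoming ambulances, plus combinations of these.
"""

from __future__ import annotations

from dataclasses import dataclass, field

UNITS = ("ed", "amu", "medical", "surgical")


@dataclass(frozen=True)
class ScenarioConfig:
    """One intervention scenario.

    ``capacity_deltas`` are signed permanent bed adjustments per unit; the
    per-episode action counts are upper bounds — an episode with fewer
    eligible patients acts on all of them and records the shortfall.
    """

    id: int
    label: str
    capacity_deltas: dict = field(default_factory=dict)
    transfer_ed_n: int = 0
    discharge_inpatient_n: int = 0
    discharge_per_class: tuple = ()  # e.g. (("medical", 1), ("surgical", 1))
    postpone_elective_n: int = 0
    divert_ambulance_n: int = 0

    def __post_init__(self):
        for n in (self.transfer_ed_n, self.discharge_inpatient_n,
                  self.postpone_elective_n, self.divert_ambulance_n):
            if n < 0:
                raise ValueError("action counts must be non-negative")

    @property
    def has_patient_actions(self) -> bool:
        return (self.transfer_ed_n + self.discharge_inpatient_n
                + self.postpone_elective_n + self.divert_ambulance_n) > 0

    def delta(self, unit: str) -> int:
        return self.capacity_deltas.get(unit, 0)


def _cap(label, id, **deltas):
    return ScenarioConfig(id=id, label=label, capacity_deltas=deltas)


def _catalog() -> dict[int, ScenarioConfig]:
    s: dict[int, ScenarioConfig] = {0: ScenarioConfig(0, "baseline (no intervention)")}
    for i, n in zip((1, 2, 3), (2, 4, 6)):
        s[i] = _cap(f"add {n} ED beds", i, ed=n)
    for i, n in zip((4, 5, 6), (2, 4, 6)):
        s[i] = _cap(f"add {n} AMU beds", i, amu=n)
    for i, n in zip((7, 8, 9), (2, 4, 6)):
        s[i] = _cap(f"move {n} surgical beds to medical", i, surgical=-n, medical=n)
    for i, n in zip((10, 11, 12), (2, 4, 6)):
        s[i] = _cap(f"move {n} medical beds to surgical", i, medical=-n, surgical=n)
    for i, n in zip((13, 14, 15), (2, 4, 6)):
        s[i] = ScenarioConfig(i, f"transfer {n} ED patients to other hospitals",
                              transfer_ed_n=n)
    for i, n in zip((16, 17, 18), (2, 4, 6)):
        s[i] = ScenarioConfig(i, f"discharge {n} inpatients early",
                              discharge_inpatient_n=n)
    for i, n in zip((19, 20, 21), (2, 4, 6)):
        s[i] = ScenarioConfig(i, f"postpone {n} elective surgeries",
                              postpone_elective_n=n)
    for i, n in zip((22, 23), (2, 4)):
        s[i] = ScenarioConfig(i, f"divert {n} ambulances", divert_ambulance_n=n)
    for i, n in zip((24, 25), (1, 2)):
        s[i] = ScenarioConfig(
            i, f"transfer {n} ED patient(s) + divert {n} ambulance(s)",
            transfer_ed_n=n, divert_ambulance_n=n)
    s[26] = ScenarioConfig(
        26,
        "transfer 1 ED patient + divert 1 ambulance + discharge 1 surgical "
        "and 1 medical inpatient",
        transfer_ed_n=1, divert_ambulance_n=1, discharge_inpatient_n=2,
        discharge_per_class=(("medical", 1), ("surgical", 1)))
    return s


_CATALOG = _catalog()
SCENARIO_IDS = tuple(sorted(_CATALOG))


def build_scenario(id: int) -> ScenarioConfig:
    """Return the scenario with the given id (0-26)."""
    try:
        return _CATALOG[id]
    except KeyError:
        raise ValueError(
            f"unknown scenario id {id}; valid ids are {SCENARIO_IDS[0]}..{SCENARIO_IDS[-1]}"
        ) from None


def all_scenarios() -> list[ScenarioConfig]:
    return [_CATALOG[i] for i in SCENARIO_IDS]


def catalog_to_yaml(path) -> None:
    """Serialise the scenario catalog (id, label, parameters) to YAML."""
    import yaml

    rows = []
    for sc in all_scenarios():
        rows.append({
            "id": sc.id,
            "label": sc.label,
            "capacity_deltas": dict(sc.capacity_deltas),
            "transfer_ed_n": sc.transfer_ed_n,
            "discharge_inpatient_n": sc.discharge_inpatient_n,
            "discharge_per_class": [list(x) for x in sc.discharge_per_class],
            "postpone_elective_n": sc.postpone_elective_n,
            "divert_ambulance_n": sc.divert_ambulance_n,
        })
    with open(path, "w") as fh:
        yaml.safe_dump(rows, fh, sort_keys=False)
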