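"""Staining-protocol schedules and total processing-time arithmetic.

Whole-mount immunostaining of gel-embedded spheroids proceeds through a
fixed sequence of stages: a methanol dehydration/rehydration series,
permeabilization + blocking, primary antibody staining (the only stage
whose duration depends on the sample), nuclear counterstaining and washes.
The module ships the three protocol families as built-in schedules — the
microwave-assisted protocol, the duration-matched benchtop protocol and
the conventional longform benchtop protocol (15 h overnight primary) — and
computes total processing times and between-protocol time ratios.

Fixation is carried out on the bench for every protocol and is stored
separately on the schedule; by convention it is excluded from the total
unless explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import yaml

STAGES = ("dehydration", "blocking", "primary", "nuclear", "wash")
METHODS = ("microwave", "benchtop", "longform")

_DEHYDRATION_SOLUTIONS = (
    "25% MeOH in 1x DPBS+/+",
    "50% MeOH in 1x DPBS+/+",
    "75% MeOH in 1x DPBS+/+",
    "95% MeOH in 1x DPBS+/+",
    "75% MeOH in 1x DPBS+/+",
    "50% MeOH in 1x DPBS+/+",
    "25% MeOH in 1x DPBS+/+",
)
_PERM = "1x DPBS+/+, 0.2% TX-100"
_BLOCK = "1x DPBS+/+, 0.2% TX-100, 1% BSA"
_PRIMARY = "1x DPBS+/+, 0.2% TX-100, 1% BSA, primary antibodies"
_NUCLEAR = "1x DPBS+/+, 0.2% TX-100, DAPI"
_WASH_SOLUTIONS = (_PERM, _PERM, "1x DPBS+/+")


@dataclass(frozen=True)
class ProtocolStep:
    stage: str
    solution: str
    minutes: float
    temperature_c: float
    method: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.minutes <= 0:
            raise ValueError("step duration must be positive")


@dataclass(frozen=True)
class ProtocolSchedule:
    name: str
    sample_type: str
    steps: tuple[ProtocolStep, ...]
    fixation_minutes: float | None = None  #: benchtop fixation, excluded from totals by default

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a schedule needs at least one step")
        order = [STAGES.index(s.stage) for s in self.steps]
        if order != sorted(order):
            raise ValueError("steps must follow the canonical stage order")


def _schedule(name, sample_type, method, dehydr, block, primary, nuclear, wash, temps, fixation):
    steps = []
    t_dehydr, t_block, t_stain = temps
    for sol, m in zip(_DEHYDRATION_SOLUTIONS, dehydr):
        steps.append(ProtocolStep("dehydration", sol, m, t_dehydr, method))
    for sol, m in zip((_PERM, _BLOCK), block):
        steps.append(ProtocolStep("blocking", sol, m, t_block, method))
    steps.append(ProtocolStep("primary", _PRIMARY, primary, t_stain, method))
    steps.append(ProtocolStep("nuclear", _NUCLEAR, nuclear, t_stain, method))
    for sol, m in zip(_WASH_SOLUTIONS, wash):
        steps.append(ProtocolStep("wash", sol, m, t_stain, method))
    return ProtocolSchedule(name, sample_type, tuple(steps), fixation)


_MICROWAVE_DEHYDR = (2, 2, 2, 4, 2, 2, 2)
_LONGFORM_DEHYDR = (30, 30, 30, 60, 30, 30, 30)


def _microwave(name, sample_type, primary, fixation):
    return _schedule(
        name, sample_type, "microwave",
        _MICROWAVE_DEHYDR, (5, 10), primary, 10, (10, 10, 5),
        temps=(10, 21, 10), fixation=fixation,
    )


def _benchtop(name, sample_type, primary, fixation):
    return _schedule(
        name, sample_type, "benchtop",
        _MICROWAVE_DEHYDR, (5, 10), primary, 10, (10, 10, 5),
        temps=(4, 21, 4), fixation=fixation,
    )


def builtin_schedules() -> dict[str, ProtocolSchedule]:
    """The built-in protocol library (primary staining time in minutes).

    Microwave and duration-matched benchtop variants for MCF10A in
    collagen (120 min primary), MCF10A in Matrigel (90 min) and MCF7 in
    collagen (40 min); the microwave protocol used in the longform
    comparison (MCF7, 120 min primary); and the conventional longform
    benchtop protocol (15 h overnight primary).  Fixation: 45 min for
    embedded MCF10A spheroids, 20 min for MCF7.
    """
    sched = {
        "microwave_mcf10a_collagen": _microwave(
            "microwave_mcf10a_collagen", "MCF10A in Collagen", 120, 45),
        "benchtop_mcf10a_collagen": _benchtop(
            "benchtop_mcf10a_collagen", "MCF10A in Collagen", 120, 45),
        "microwave_mcf10a_matrigel": _microwave(
            "microwave_mcf10a_matrigel", "MCF10A in Matrigel", 90, 45),
        "benchtop_mcf10a_matrigel": _benchtop(
            "benchtop_mcf10a_matrigel", "MCF10A in Matrigel", 90, 45),
        "microwave_mcf7_collagen": _microwave(
            "microwave_mcf7_collagen", "MCF7 in Collagen", 40, 20),
        "benchtop_mcf7_collagen": _benchtop(
            "benchtop_mcf7_collagen", "MCF7 in Collagen", 40, 20),
        "microwave_mcf7_longform_comparison": _microwave(
            "microwave_mcf7_longform_comparison", "MCF7 in Collagen (Longform)", 120, 20),
        "longform_benchtop_mcf7": _schedule(
            "longform_benchtop_mcf7", "MCF7 in Collagen (Longform)", "longform",
            _LONGFORM_DEHYDR, (5, 60), 15 * 60, 30, (30, 30, 5),
            temps=(4, 4, 4), fixation=20),
    }
    return sched


@dataclass(frozen=True)
class TotalDuration:
    minutes: float
    hours: float  #: rounded half-up to one decimal
    includes_fixation: bool


def total_duration(schedule: ProtocolSchedule, include_fixation: bool = False) -> TotalDuration:
    """Sum of step durations; fixation added only when requested."""
    minutes = float(sum(s.minutes for s in schedule.steps))
    if include_fixation:
        if schedule.fixation_minutes is None:
            raise ValueError(f"schedule {schedule.name!r} records no fixation duration")
        minutes += float(schedule.fixation_minutes)
    hours = float(Decimal(minutes / 60.0).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return TotalDuration(minutes=minutes, hours=hours, includes_fixation=include_fixation)


def compare_schedules(
    a: ProtocolSchedule,
    b: ProtocolSchedule,
    include_fixation: bool = False,
    ndigits: int | None = 1,
) -> float:
    """Ratio of total processing times, total(b) / total(a)."""
    ta = total_duration(a, include_fixation).minutes
    tb = total_duration(b, include_fixation).minutes
    if ta <= 0 or tb <= 0:
        raise ValueError("schedule totals must be positive")
    ratio = tb / ta
    return round(ratio, ndigits) if ndigits is not None else ratio


# ---------------------------------------------------------------------------
# plain-text schedule files

def schedule_to_dict(schedule: ProtocolSchedule) -> dict:
    return {
        "name": schedule.name,
        "sample_type": schedule.sample_type,
        "fixation_minutes": schedule.fixation_minutes,
        "steps": [
            {
                "stage": s.stage,
                "solution": s.solution,
                "minutes": s.minutes,
                "temperature_c": s.temperature_c,
                "method": s.method,
            }
            for s in schedule.steps
        ],
    }


def schedule_from_dict(d: dict) -> ProtocolSchedule:
    steps = tuple(
        ProtocolStep(
            stage=s["stage"],
            solution=s["solution"],
            minutes=s["minutes"],
            temperature_c=s["temperature_c"],
            method=s["method"],
        )
        for s in d["steps"]
    )
    return ProtocolSchedule(
        name=d["name"],
        sample_type=d["sample_type"],
        steps=steps,
        fixation_minutes=d.get("fixation_minutes"),
    )


def write_schedule(schedule: ProtocolSchedule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule_to_dict(schedule), fh, sort_keys=False)


def read_schedule(path) -> ProtocolSchedule:
    with open(path) as fh:
        return schedule_from_dict(yaml.safe_load(fh))
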