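"""Condition presets for the synthetic scene generator.

The magnitudes below are deliberate artifact choices that emulate the
*direction* of published genotoxin effects on single-cell readouts; they are
not measured values. ``untreated`` and ``dart_e160a`` (catalytically dead
toxin) are identity presets. Effects are expressed per cell-cycle phase as a
multiplicative factor and/or an additive term applied to the baseline channel
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import ValidationError

PHASES = ("G1", "S", "G2")

#: Baseline per-phase channel means (arbitrary units) for an untreated cell.
#: EdU marks active synthesis (high only in S); chromatin-bound PCNA marks
#: S-phase with >=4x separation over the out-of-S level so marker-based
#: S-calling is well posed; damage/ADP-ribose channels start at a low floor.
BASE_CHANNEL_MEANS: dict[str, dict[str, float]] = {
    "EdU": {"G1": 10.0, "S": 400.0, "G2": 10.0},
    "PCNA": {"G1": 50.0, "S": 500.0, "G2": 50.0},
    "gH2AX": {"G1": 30.0, "S": 30.0, "G2": 30.0},
    "RPA2": {"G1": 25.0, "S": 25.0, "G2": 25.0},
    "ADPr": {"G1": 30.0, "S": 30.0, "G2": 30.0},
}

DEFAULT_CHANNELS = ("DAPI", "EdU", "PCNA", "gH2AX", "RPA2", "ADPr")


@dataclass(frozen=True)
class ConditionPreset:
    """Per-phase effect of one experimental condition on channel means.

    ``scale[channel][phase]`` multiplies the baseline mean (default 1);
    ``shift[channel][phase]`` is added afterwards (default 0).
    """

    name: str
    scale: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    shift: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table, what in ((self.scale, "scale"), (self.shift, "shift")):
            for channel, per_phase in table.items():
                for phase, value in per_phase.items():
                    if phase not in PHASES:
                        raise ValidationError(
                            f"preset {self.name!r}: unknown phase {phase!r}"
                        )
                    if value < 0:
                        raise ValidationError(
                            f"preset {self.name!r}: negative {what} for "
                            f"{channel}/{phase}"
                        )

    def mean(self, channel: str, phase: str, base: float) -> float:
        factor = self.scale.get(channel, {}).get(phase, 1.0)
        term = self.shift.get(channel, {}).get(phase, 0.0)
        return base * factor + term


PRESETS: dict[str, ConditionPreset] = {
    "untreated": ConditionPreset("untreated"),
    "dart_e160a": ConditionPreset("dart_e160a"),
    # Active toxin: S-phase-restricted replication slowdown, damage signalling
    # and DNA ADP-ribosylation at replication sites.
    "dart_wt": ConditionPreset(
        "dart_wt",
        scale={"EdU": {"S": 0.3}},
        shift={
            "gH2AX": {"S": 250.0},
            "RPA2": {"S": 250.0},
            "ADPr": {"S": 200.0},
        },
    ),
    # Replication inhibitor: synthesis nearly abolished in S.
    "hu": ConditionPreset(
        "hu",
        scale={"EdU": {"S": 0.02}},
        shift={"gH2AX": {"S": 80.0}, "RPA2": {"S": 120.0}},
    ),
    # Topoisomerase poison: replication-linked damage, partial slowdown.
    "cpt": ConditionPreset(
        "cpt",
        scale={"EdU": {"S": 0.5}},
        shift={"gH2AX": {"S": 100.0}, "RPA2": {"S": 140.0}},
    ),
    # Alkylating agent: ADP-ribosylation in every phase, mild S slowdown.
    "mms": ConditionPreset(
        "mms",
        scale={"EdU": {"S": 0.6}},
        shift={
            "ADPr": {"G1": 120.0, "S": 120.0, "G2": 120.0},
            "gH2AX": {"S": 40.0},
        },
    ),
}


def get_preset(name: str) -> ConditionPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValidationError(
            f"unknown condition preset {name!r}; known: {sorted(PRESETS)}"
        ) from None
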