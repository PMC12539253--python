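"""Screw and planetary-gear kinematics for micron-precision probe positioning.

A microdrive implant moves its probe shuttle along a fine-pitch drive screw
(linear travel per full rotation = thread pitch ``P``).  Because turning a
small screw a fifth of a turn by hand is impractical, the drive screw is
turned through a geared screwdriver built from cascaded planetary stages:
the sun gear is the input, the carrier the output, and the ring gear is held
fixed, giving a per-stage turn ratio of ``S / (R + S)`` (sun teeth over ring
plus sun teeth).  Two 5:1 stages cascade into a 25:1 train, so one input
turn advances a 0.3 mm pitch screw by 12 μm.

Turn ratios are stored as exact :class:`fractions.Fraction` values so the
25:1 train is exact and cumulative ledger sums cannot drift; conversion to
floating point happens only at the millimetre boundary.

Sign convention: positive turns are counterclockwise at the drive screw and
extend the probe out of the implant base (descend into tissue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

__all__ = [
    "ScrewSpec",
    "GearStage",
    "GearTrain",
    "DriveConfig",
    "GearParameterError",
    "GearGeometryWarning",
    "stage_turn_ratio",
    "train_turn_ratio",
    "distance_from_turns",
    "turns_for_distance",
    "distance_from_input_turns",
    "input_turns_for_distance",
    "KIT_SCREW",
    "KIT_TRAIN",
    "KIT_DRIVE",
    "COUNTER_STAGE",
]


class GearParameterError(ValueError):
    """Raised for physically impossible screw or gear parameters."""


class GearGeometryWarning(UserWarning):
    """Tooth counts are ratio-consistent but geometrically implausible."""


@dataclass(frozen=True)
class ScrewSpec:
    """Drive screw: ``pitch_mm`` is linear travel per full rotation."""

    pitch_mm: float

    def __post_init__(self) -> None:
        if not self.pitch_mm > 0:
            raise GearParameterError(
                f"screw pitch must be positive, got {self.pitch_mm!r} mm"
            )


@dataclass(frozen=True)
class GearStage:
    """One planetary stage: fixed ring, sun input, carrier output.

    ``planet_teeth`` is informational — the turn ratio depends only on sun
    and ring counts — but when given it is checked against the meshing
    constraint ``ring = sun + 2 * planet`` (a violation warns, it does not
    raise, since the ratio is still well defined).
    """

    sun_teeth: int
    ring_teeth: int
    planet_teeth: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("sun_teeth", "ring_teeth"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 1:
                raise GearParameterError(
                    f"{name} must be a positive integer, got {value!r}"
                )
        if self.planet_teeth is not None:
            if not isinstance(self.planet_teeth, int) or self.planet_teeth < 1:
                raise GearParameterError(
                    f"planet_teeth must be a positive integer, got {self.planet_teeth!r}"
                )
            if self.ring_teeth != self.sun_teeth + 2 * self.planet_teeth:
                warnings.warn(
                    "tooth counts violate the planetary meshing constraint "
                    f"ring = sun + 2*planet ({self.ring_teeth} != "
                    f"{self.sun_teeth} + 2*{self.planet_teeth})",
                    GearGeometryWarning,
                    stacklevel=2,
                )

    @property
    def turn_ratio(self) -> Fraction:
        return stage_turn_ratio(self)


@dataclass(frozen=True)
class GearTrain:
    """Ordered cascade of planetary stages; an empty train is direct drive."""

    stages: tuple[GearStage, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "stages", tuple(self.stages))

    @property
    def turn_ratio(self) -> Fraction:
        return train_turn_ratio(self)


@dataclass(frozen=True)
class DriveConfig:
    """Screw plus screwdriver gear train; the complete drive kinematics."""

    screw: ScrewSpec
    train: GearTrain = field(default_factory=GearTrain)

    @property
    def min_step_mm(self) -> float:
        """Shuttle travel for one whole input turn (pitch × turn ratio)."""
        return distance_from_input_turns(self, 1.0)


def stage_turn_ratio(stage: GearStage) -> Fraction:
    """Output turns per input turn of one planetary stage, ``S / (R + S)``.

    Exact rational arithmetic; strictly in (0, 1).
    """
    return Fraction(stage.sun_teeth, stage.ring_teeth + stage.sun_teeth)


def train_turn_ratio(train: GearTrain) -> Fraction:
    """Output turns per input turn of the cascade: product of stage ratios."""
    ratio = Fraction(1)
    for stage in train.stages:
        ratio *= stage_turn_ratio(stage)
    return ratio


def distance_from_turns(screw: ScrewSpec, turns: float) -> float:
    """Shuttle travel (mm) for ``turns`` direct rotations of the drive screw."""
    return screw.pitch_mm * turns


def turns_for_distance(screw: ScrewSpec, distance_mm: float) -> float:
    """Direct screw turns needed for a given shuttle travel (mm)."""
    return distance_mm / screw.pitch_mm


def distance_from_input_turns(config: DriveConfig, input_turns: float) -> float:
    """Shuttle travel (mm) for turns applied at the geared screwdriver input."""
    ratio = config.train.turn_ratio
    # Multiply in rational space first so e.g. 10 turns / 25:1 stays exact.
    return float(Fraction(ratio) * input_turns * config.screw.pitch_mm)


def input_turns_for_distance(config: DriveConfig, distance_mm: float) -> float:
    """Geared-input turns needed for a given shuttle travel (mm)."""
    ratio = config.train.turn_ratio
    if ratio <= 0:
        raise GearParameterError("gear train turn ratio must be positive")
    return float(distance_mm / (config.screw.pitch_mm * Fraction(ratio)))


#: The kit's 0.3 mm pitch drive screw (M1.4x12).
KIT_SCREW = ScrewSpec(pitch_mm=0.3)

#: Two cascaded 5:1 planetary stages (sun 8, ring 32, planets 12) -> 25:1.
KIT_TRAIN = GearTrain(
    stages=(
        GearStage(sun_teeth=8, ring_teeth=32, planet_teeth=12),
        GearStage(sun_teeth=8, ring_teeth=32, planet_teeth=12),
    )
)

#: Default drive: 0.012 mm of shuttle travel per whole input turn.
KIT_DRIVE = DriveConfig(screw=KIT_SCREW, train=KIT_TRAIN)

#: The turn-counter attachment's 10:1 stage (sun 5, planets 20, ring 45).
#: It displays input turns and does not contribute to the drive ratio.
COUNTER_STAGE = GearStage(sun_teeth=5, ring_teeth=45, planet_teeth=20)
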