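"""Probe-depth tracking from implantation through post-surgical adjustments.

The probe tip's dorsoventral (DV) coordinate is negative below the brain
surface.  At surgery the shank is drawn out of the implant by

    L0 = |DV0| + A + B

where ``DV0`` is the target initial implantation depth, ``A`` the measured
skull thickness and ``B`` the implant's bottom-wall thickness (0.5 mm by
default), so that lowering the implant onto the skull puts the tip at
``DV0``.  Every later micro-adjustment ``D_i`` (signed mm, negative =
deeper) is appended to an append-only ledger, and the current tip depth is
always the recomputable sum

    DV = DV0 + sum(D_i).

Adjustments may be entered as a distance or as screwdriver turns ("direct"
at the drive screw, or "geared" through the planetary screwdriver); the
missing quantity is derived from the ledger's drive kinematics.

A calibration procedure corrects 3D-printing tolerance: with the implant on
a calibration block, ten counterclockwise screw turns should displace the
tip exactly 3 mm to a reference mark.  The surplus turns needed to actually
reach the mark are the error turns ``ET``; their linear equivalent
``ED = pitch × ET`` is the print-tolerance gap, and pre-turning ``ET`` after
full retraction zeroes it out.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

from .gears import (
    DriveConfig,
    ScrewSpec,
    GearStage,
    GearTrain,
    distance_from_turns,
    turns_for_distance,
)

__all__ = [
    "ImplantGeometry",
    "AdjustmentRecord",
    "DepthLedger",
    "CalibrationResult",
    "ShankLimitError",
    "LedgerError",
    "initial_draw_length",
    "draw_turns",
    "calibration_error",
    "DEFAULT_USABLE_SHANK_MM",
]

#: Usable shank length: 10 mm probe shank minus the 0.5 mm bottom wall.
DEFAULT_USABLE_SHANK_MM = 9.5

#: Adjustment modes: turns applied directly at the drive screw, or at the
#: input of the planetary-geared screwdriver.
MODES = ("direct", "geared")


class LedgerError(ValueError):
    """Invalid ledger operation or malformed persisted ledger."""


class ShankLimitError(LedgerError):
    """Requested depth would exceed the usable probe-shank length."""


@dataclass(frozen=True)
class ImplantGeometry:
    """Skull thickness ``A`` and implant bottom-wall thickness ``B`` (mm)."""

    skull_thickness_mm: float
    base_wall_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.skull_thickness_mm < 0 or self.base_wall_mm < 0:
            raise LedgerError("geometry thicknesses must be non-negative")


@dataclass(frozen=True)
class AdjustmentRecord:
    """One post-surgical micro-adjustment.

    ``distance_mm`` is the signed tip displacement (negative = deeper);
    ``turns`` is the signed turn count that produced it (positive =
    counterclockwise = deeper) in the given ``mode``.
    """

    index: int
    mode: str
    turns: float
    distance_mm: float
    note: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise LedgerError(f"mode must be one of {MODES}, got {self.mode!r}")
        object.__setattr__(self, "turns", float(self.turns))
        object.__setattr__(self, "distance_mm", float(self.distance_mm))


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the calibration-block procedure."""

    reference_turns: float
    counted_turns: float
    error_turns: float
    error_distance_mm: float


def initial_draw_length(
    dv0_mm: float,
    geometry: ImplantGeometry,
    max_draw_mm: float = DEFAULT_USABLE_SHANK_MM,
) -> float:
    """Shank draw length L0 = |DV0| + A + B (mm).

    Raises :class:`ShankLimitError` if the draw would exceed the usable
    shank length (default 9.5 mm: the 10 mm shank minus the bottom wall).
    """
    l0 = abs(dv0_mm) + geometry.skull_thickness_mm + geometry.base_wall_mm
    if l0 > max_draw_mm:
        raise ShankLimitError(
            f"draw length {l0:.3f} mm exceeds the usable shank length "
            f"{max_draw_mm:.3f} mm; choose a shallower initial depth"
        )
    return l0


def draw_turns(l0_mm: float, screw: ScrewSpec) -> float:
    """Direct drive-screw turns to draw the shank out by ``l0_mm``."""
    return turns_for_distance(screw, l0_mm)


def calibration_error(
    counted_turns: float,
    screw: ScrewSpec,
    reference_turns: float = 10.0,
) -> CalibrationResult:
    """Quantify print-tolerance error from the calibration-block count.

    ``counted_turns`` is the total counterclockwise turns until the tip
    aligned with the reference mark; the first ``reference_turns`` (default
    10, i.e. 3 mm at 0.3 mm pitch) are the nominal displacement, the
    surplus is the error ``ET`` with linear equivalent ``ED = pitch × ET``.
    The corrective pre-offset to apply after full retraction is ``ET`` turns.
    """
    if reference_turns < 0:
        raise LedgerError("reference_turns must be non-negative")
    if counted_turns < reference_turns:
        raise LedgerError(
            f"counted turns ({counted_turns}) fewer than the reference count "
            f"({reference_turns}): the mark was overshot before the reference "
            "displacement completed; re-run the calibration"
        )
    et = counted_turns - reference_turns
    return CalibrationResult(
        reference_turns=reference_turns,
        counted_turns=counted_turns,
        error_turns=et,
        error_distance_mm=distance_from_turns(screw, et),
    )


class DepthLedger:
    """Append-only record of probe-tip depth.

    Parameters
    ----------
    dv0_mm
        Initial implantation depth (negative below the surface).
    geometry
        Skull and implant wall thicknesses used for the draw length.
    drive
        Screw and gear-train kinematics used to convert turns <-> distance.
    usable_shank_mm
        Guard limit on total shank extension (draw length + descent).
    """

    def __init__(
        self,
        dv0_mm: float,
        geometry: ImplantGeometry,
        drive: DriveConfig,
        usable_shank_mm: float = DEFAULT_USABLE_SHANK_MM,
    ) -> None:
        self.dv0_mm = float(dv0_mm)
        self.geometry = geometry
        self.drive = drive
        self.usable_shank_mm = float(usable_shank_mm)
        self._adjustments: list[AdjustmentRecord] = []
        # Validate the implied draw length up front.
        initial_draw_length(self.dv0_mm, geometry, self.usable_shank_mm)

    # -- core bookkeeping --------------------------------------------------

    @property
    def adjustments(self) -> tuple[AdjustmentRecord, ...]:
        return tuple(self._adjustments)

    def current_depth(self) -> float:
        """Tip depth DV = DV0 + sum of adjustment distances (recomputed)."""
        return self.dv0_mm + math.fsum(r.distance_mm for r in self._adjustments)

    def _step_mm(self, mode: str) -> float:
        """Linear travel per whole turn in the given mode."""
        if mode == "direct":
            return distance_from_turns(self.drive.screw, 1.0)
        if mode == "geared":
            return self.drive.min_step_mm
        raise LedgerError(f"mode must be one of {MODES}, got {mode!r}")

    def record_adjustment(
        self,
        distance_mm: Optional[float] = None,
        turns: Optional[float] = None,
        mode: str = "geared",
        note: str = "",
    ) -> AdjustmentRecord:
        """Append one micro-adjustment, given distance OR turns (not both).

        Positive turns (counterclockwise) descend, so the derived distance
        is negative; positive ``distance_mm`` retracts.  The resulting depth
        must stay within the usable shank length.
        """
        if (distance_mm is None) == (turns is None):
            raise LedgerError("give exactly one of distance_mm or turns")
        step = self._step_mm(mode)
        if turns is None:
            turns = -distance_mm / step
        else:
            distance_mm = -turns * step
        new_depth = self.current_depth() + distance_mm
        extension = (
            abs(new_depth)
            + self.geometry.skull_thickness_mm
            + self.geometry.base_wall_mm
        )
        if extension > self.usable_shank_mm:
            raise ShankLimitError(
                f"adjustment would extend the shank to {extension:.3f} mm, "
                f"beyond the usable {self.usable_shank_mm:.3f} mm"
            )
        record = AdjustmentRecord(
            index=len(self._adjustments),
            mode=mode,
            turns=turns,
            distance_mm=distance_mm,
            note=note,
        )
        self._adjustments.append(record)
        return record

    # -- planning ----------------------------------------------------------

    def plan_adjustment(
        self, target_dv_mm: float, resolution_turns: float = 1.0
    ) -> tuple[float, float, float]:
        """Turns needed to move the tip toward ``target_dv_mm``.

        Returns ``(input_turns, achieved_dv_mm, residual_mm)`` where the
        geared input turns are quantized to ``resolution_turns`` (1.0 =
        whole turns as counted by the counter disk; 0.25 matches the
        quarter-turn marks on the counter knob), rounding ties toward fewer
        turns; ``|residual| <= min_step * resolution / 2``.
        """
        if resolution_turns <= 0:
            raise LedgerError("resolution_turns must be positive")
        step = self.drive.min_step_mm * resolution_turns
        current = self.current_depth()
        exact = (current - target_dv_mm) / step  # positive = descend
        magnitude = abs(exact)
        quanta = math.floor(magnitude)
        frac = magnitude - quanta
        # Nearest whole count; a half-step tie (within float fuzz) keeps the
        # smaller count, i.e. fewer turns.
        if frac > 0.5 + 1e-9:
            quanta += 1
        turns = math.copysign(quanta * resolution_turns, exact) if quanta else 0.0
        achieved = current - turns * self.drive.min_step_mm
        if (
            abs(achieved)
            + self.geometry.skull_thickness_mm
            + self.geometry.base_wall_mm
            > self.usable_shank_mm
        ):
            raise ShankLimitError(
                f"target {target_dv_mm:.3f} mm DV is beyond the usable shank length"
            )
        residual = target_dv_mm - achieved
        return turns, achieved, residual

    def electrode_row_depth(
        self, row_index: int, row_pitch_mm: float, tip_offset_mm: float = 0.0
    ) -> float:
        """DV of electrode row ``row_index``, counted up from the tip.

        Rows sit shallower than the tip: row 0 is ``tip_offset_mm`` above
        the tip, successive rows a further ``row_pitch_mm`` each.  Pad size
        and spacing come from the probe datasheet.
        """
        if row_index < 0:
            raise LedgerError("row_index must be non-negative")
        return self.current_depth() + tip_offset_mm + row_index * row_pitch_mm

    # -- persistence ---------------------------------------------------------

    _META_KEYS = (
        "dv0_mm",
        "skull_thickness_mm",
        "base_wall_mm",
        "pitch_mm",
        "stages",
        "usable_shank_mm",
    )

    def to_csv(self, path: Union[str, Path]) -> None:
        """Persist as CSV: '#'-prefixed metadata lines, then one row per
        adjustment with the running cumulative depth.

        Floats are serialized with ``repr`` so the round trip is
        bit-identical.
        """
        path = Path(path)
        stages = ";".join(
            f"{s.sun_teeth}:{s.ring_teeth}:{s.planet_teeth if s.planet_teeth is not None else ''}"
            for s in self.drive.train.stages
        )
        meta = {
            "dv0_mm": repr(self.dv0_mm),
            "skull_thickness_mm": repr(self.geometry.skull_thickness_mm),
            "base_wall_mm": repr(self.geometry.base_wall_mm),
            "pitch_mm": repr(self.drive.screw.pitch_mm),
            "stages": stages,
            "usable_shank_mm": repr(self.usable_shank_mm),
        }
        with path.open("w", newline="") as fh:
            for key in self._META_KEYS:
                fh.write(f"# {key}={meta[key]}\n")
            writer = csv.writer(fh)
            writer.writerow(
                ["index", "mode", "turns", "distance_mm", "cumulative_dv_mm", "note"]
            )
            cumulative = self.dv0_mm
            for rec in self._adjustments:
                cumulative += rec.distance_mm
                writer.writerow(
                    [
                        rec.index,
                        rec.mode,
                        repr(rec.turns),
                        repr(rec.distance_mm),
                        repr(cumulative),
                        rec.note,
                    ]
                )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DepthLedger":
        """Rebuild a ledger persisted by :meth:`to_csv`."""
        path = Path(path)
        meta: dict[str, str] = {}
        rows: list[list[str]] = []
        with path.open(newline="") as fh:
            header: Optional[list[str]] = None
            for line in fh:
                if line.startswith("#"):
                    key, _, value = line[1:].strip().partition("=")
                    meta[key.strip()] = value
                    continue
                parsed = next(csv.reader([line]))
                if header is None:
                    header = parsed
                    continue
                if parsed:
                    rows.append(parsed)
        missing = [k for k in cls._META_KEYS if k not in meta]
        if missing:
            raise LedgerError(f"ledger file {path} is missing metadata: {missing}")
        stages = []
        if meta["stages"]:
            for chunk in meta["stages"].split(";"):
                sun, ring, planet = chunk.split(":")
                stages.append(
                    GearStage(
                        sun_teeth=int(sun),
                        ring_teeth=int(ring),
                        planet_teeth=int(planet) if planet else None,
                    )
                )
        ledger = cls(
            dv0_mm=float(meta["dv0_mm"]),
            geometry=ImplantGeometry(
                skull_thickness_mm=float(meta["skull_thickness_mm"]),
                base_wall_mm=float(meta["base_wall_mm"]),
            ),
            drive=DriveConfig(
                screw=ScrewSpec(pitch_mm=float(meta["pitch_mm"])),
                train=GearTrain(stages=tuple(stages)),
            ),
            usable_shank_mm=float(meta["usable_shank_mm"]),
        )
        for row in rows:
            index, mode, turns, distance_mm, cumulative, note = row
            rec = AdjustmentRecord(
                index=int(index),
                mode=mode,
                turns=float(turns),
                distance_mm=float(distance_mm),
                note=note,
            )
            kinematic = abs(rec.turns) * ledger._step_mm(mode)
            if abs(kinematic - abs(rec.distance_mm)) > 1e-9:
                raise LedgerError(
                    f"record {index}: |distance| {abs(rec.distance_mm)!r} mm does "
                    f"not match {rec.turns!r} {mode} turns ({kinematic!r} mm)"
                )
            ledger._adjustments.append(rec)
        return ledger
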