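"""Stimulus level scales and the staircase ladder.

The recording device is driven on a dB HL dial.  For the short 750 Hz tone
burst used here the dial value maps onto three other scales by fixed affine
offsets that depend on the transducer:

* dB nHL  -- normal hearing level for the tone burst (dial minus the RETSPL
  correction): ``HL - 14`` for the B71 bone vibrator, ``HL - 12`` for TDH39
  headphones.
* dB FL   -- force level at the artificial mastoid (bone conduction only):
  ``HL + 49``.
* dB SPL  -- peak-to-peak equivalent sound pressure level in the artificial
  ear (air conduction only): ``HL + 9``.

Offsets are stored as named per-mode constants; deriving them from the
IEC/ISO calibration standards is out of scope.  Conversions accept any float;
only the staircase validates the 5-dB grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

class Conduction(str, Enum):
    """Stimulus delivery route."""

    AC = "AC"  # air conduction, TDH39 headphones
    BC = "BC"  # bone conduction, B71 vibrator on the mastoid

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: dB HL -> dB nHL: subtract this per-mode RETSPL correction (750 Hz tone burst).
NHL_OFFSET_DB = {Conduction.BC: 14.0, Conduction.AC: 12.0}

#: dB HL -> physical scale: add this per-mode offset.
PHYSICAL_OFFSET_DB = {Conduction.BC: 49.0, Conduction.AC: 9.0}

#: Name of the physical scale defined for each mode.
PHYSICAL_SCALE = {Conduction.BC: "FL", Conduction.AC: "SPL"}

#: Dial range of the recording device, dB HL.
DEVICE_RANGE_DB_HL = (0.0, 110.0)


def _as_mode(mode) -> Conduction:
    try:
        return Conduction(mode)
    except ValueError:
        raise ValueError(f"unknown conduction mode: {mode!r}") from None


@dataclass(frozen=True)
class LevelValue:
    """A stimulus level tagged with the dB scale it lives on."""

    value: float
    scale: str  # one of "HL", "nHL", "FL", "SPL"

    _SCALES = ("HL", "nHL", "FL", "SPL")

    def __post_init__(self) -> None:
        if self.scale not in self._SCALES:
            raise ValueError(f"unknown level scale: {self.scale!r}")


@dataclass(frozen=True)
class StimulusSpec:
    """Tone-burst stimulus description.

    Defaults are the pediatric c-VEMP protocol: 750 Hz, 4 ms with one cycle
    each of rise/plateau/fall, delivered at 4 per second.
    """

    mode: Conduction
    level_hl: float
    frequency_hz: float = 750.0
    duration_ms: float = 4.0
    envelope_cycles: tuple[int, int, int] = (1, 1, 1)
    rate_pps: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", _as_mode(self.mode))
        if self.frequency_hz <= 0:
            raise ValueError("frequency must be positive")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        lo, hi = DEVICE_RANGE_DB_HL
        if not lo <= self.level_hl <= hi:
            raise ValueError(
                f"level {self.level_hl} dB HL outside device range {DEVICE_RANGE_DB_HL}"
            )

    @property
    def level_nhl(self) -> float:
        return hl_to_nhl(self.mode, self.level_hl)

    @property
    def level_physical(self) -> LevelValue:
        return hl_to_physical(self.mode, self.level_hl)


def hl_to_nhl(mode, level_hl: float) -> float:
    """Convert a dial level in dB HL to dB nHL for the given transducer."""
    return float(level_hl) - NHL_OFFSET_DB[_as_mode(mode)]


def nhl_to_hl(mode, level_nhl: float) -> float:
    """Inverse of :func:`hl_to_nhl`."""
    return float(level_nhl) + NHL_OFFSET_DB[_as_mode(mode)]


def hl_to_physical(mode, level_hl: float) -> LevelValue:
    """Convert dB HL to the mode's physical scale (dB FL for BC, dB SPL for AC)."""
    mode = _as_mode(mode)
    return LevelValue(float(level_hl) + PHYSICAL_OFFSET_DB[mode], PHYSICAL_SCALE[mode])


def physical_to_hl(mode, level) -> float:
    """Inverse of :func:`hl_to_physical`; accepts a float or a LevelValue."""
    mode = _as_mode(mode)
    if isinstance(level, LevelValue):
        if level.scale != PHYSICAL_SCALE[mode]:
            raise ValueError(
                f"scale {level.scale!r} is not the physical scale of mode {mode}"
            )
        level = level.value
    return float(level) - PHYSICAL_OFFSET_DB[mode]


@dataclass(frozen=True)
class Staircase:
    """Descending level ladder plus the ascending branch for no-response starts."""

    descending: tuple[float, ...]
    ascending: tuple[float, ...]

    @property
    def all_levels(self) -> tuple[float, ...]:
        return tuple(sorted(set(self.descending) | set(self.ascending)))


def staircase_levels(
    start: float, step: float = 5.0, floor: float = 60.0, ceiling: float = 110.0
) -> Staircase:
    """Build the 5-dB staircase around a starting level.

    The descending branch runs ``start, start-step, ...`` down to ``floor``;
    the ascending branch (used when there is no response at the start) runs
    ``start+step, ...`` up to ``ceiling``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if floor > ceiling:
        raise ValueError("floor must not exceed ceiling")
    if not floor <= start <= ceiling:
        raise ValueError("start level must lie within [floor, ceiling]")
    down, level = [], start
    while level >= floor - 1e-9:
        down.append(round(level, 6))
        level -= step
    up, level = [], start + step
    while level <= ceiling + 1e-9:
        up.append(round(level, 6))
        level += step
    return Staircase(tuple(down), tuple(up))


@dataclass(frozen=True)
class StaircaseProtocol:
    """Threshold-search protocol on the dB HL dial.

    ``start_level_hl`` 100 dB HL is the reference level of the recording
    protocol (86 dB nHL for BC, 88 dB nHL for AC); the device ceiling is
    110 dB HL.  The device floor is not critical -- it sits below every
    observed threshold -- and defaults to 60 dB HL.
    """

    start_level_hl: float = 100.0
    step_db: float = 5.0
    max_level_hl: float = 110.0
    floor_level_hl: float = 60.0

    def ladder_hl(self) -> Staircase:
        return staircase_levels(
            self.start_level_hl, self.step_db, self.floor_level_hl, self.max_level_hl
        )

    def ladder_nhl(self, mode) -> Staircase:
        lad = self.ladder_hl()
        conv = lambda seq: tuple(hl_to_nhl(mode, x) for x in seq)  # noqa: E731
        return Staircase(conv(lad.descending), conv(lad.ascending))

    def reference_nhl(self, mode) -> float:
        return hl_to_nhl(mode, self.start_level_hl)

    def ceiling_nhl(self, mode) -> float:
        return hl_to_nhl(mode, self.max_level_hl)

    def floor_nhl(self, mode) -> float:
        return hl_to_nhl(mode, self.floor_level_hl)

    def snap_nhl(self, mode, level_nhl: float) -> float:
        """Snap an arbitrary dB nHL value onto this protocol's ladder grid."""
        ref = self.reference_nhl(mode)
        snapped = ref + round((level_nhl - ref) / self.step_db) * self.step_db
        lo, hi = self.floor_nhl(mode), self.ceiling_nhl(mode)
        return float(min(max(snapped, lo), hi))
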