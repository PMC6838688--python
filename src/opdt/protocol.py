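"""Stimulus designs for the population-discharge threshold procedure.

Two designs are used: randomized-block single-pulse intensity series (one
presentation of every intensity level per block, block order independently
randomized) and fixed-frequency pulse trains for afterdischarge induction.

Intensities live on an arbitrary linearized level scale (1..L) paired with a
per-level optical-power calibration (mW at the fiber tip).  The level scale is
the default x-axis for curve fitting; conversion to mW is a piecewise-linear
interpolation of the calibration table.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, RangeError

__all__ = [
    "IntensityScale",
    "StimulusEvent",
    "PulseProtocol",
    "TrainProtocol",
    "make_pulse_protocol",
    "make_train_protocol",
    "level_power_map",
    "write_protocol",
    "read_protocol",
]


@dataclass(frozen=True)
class IntensityScale:
    """Calibrated mapping between integer intensity levels and optical power.

    Parameters
    ----------
    levels
        Ordered integer level indices, strictly increasing (typically 1..20).
    power_mW
        Optical power at the fiber tip for each level, strictly increasing.
    """

    levels: tuple[int, ...]
    power_mW: tuple[float, ...]

    def __post_init__(self) -> None:
        levels = tuple(int(v) for v in self.levels)
        power = tuple(float(v) for v in self.power_mW)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "power_mW", power)
        if len(levels) != len(power):
            raise InvalidArgumentError("levels and power_mW must have equal length")
        if len(levels) < 2:
            raise InvalidArgumentError("an intensity scale needs at least 2 levels")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise InvalidArgumentError("levels must be strictly increasing")
        if any(b <= a for a, b in zip(power, power[1:])):
            raise InvalidArgumentError("power_mW must be strictly increasing")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @classmethod
    def default(cls, n_levels: int = 20, p_min_mW: float = 0.43,
                p_max_mW: float = 4.15) -> "IntensityScale":
        """Twenty equally spaced levels spanning 0.43-4.15 mW unless overridden."""
        return cls(tuple(range(1, n_levels + 1)),
                   tuple(np.linspace(p_min_mW, p_max_mW, n_levels)))


@dataclass(frozen=True)
class StimulusEvent:
    """One light pulse within a protocol."""

    block_index: int
    within_block_index: int
    level: int
    power_mW: float
    onset_s: float
    pulse_width_ms: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise InvalidArgumentError("event onset must be non-negative")


@dataclass(frozen=True)
class PulseProtocol:
    """Randomized-block single-pulse intensity series."""

    scale: IntensityScale
    n_blocks: int
    isi_s: float
    pulse_width_ms: float
    seed: int
    events: tuple[StimulusEvent, ...]

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def levels(self) -> np.ndarray:
        return np.array([e.level for e in self.events], dtype=int)

    @property
    def blocks(self) -> np.ndarray:
        return np.array([e.block_index for e in self.events], dtype=int)

    @property
    def onsets_s(self) -> np.ndarray:
        return np.array([e.onset_s for e in self.events], dtype=float)

    @property
    def duration_s(self) -> float:
        """Onset-to-onset span of the design plus one trailing ISI."""
        return self.n_events * self.isi_s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": [e.block_index for e in self.events],
                "idx": [e.within_block_index for e in self.events],
                "level": [e.level for e in self.events],
                "power_mW": [e.power_mW for e in self.events],
                "onset_s": [e.onset_s for e in self.events],
                "pulse_width_ms": [e.pulse_width_ms for e in self.events],
            }
        )


@dataclass(frozen=True)
class TrainProtocol:
    """Fixed-frequency stimulus train (afterdischarge induction)."""

    frequency_hz: float
    duration_s: float
    pulse_width_ms: float
    power_mW: float
    period_s: float
    pulse_onsets_s: tuple[float, ...]

    @property
    def n_pulses(self) -> int:
        return len(self.pulse_onsets_s)

    @property
    def is_empty(self) -> bool:
        return self.n_pulses == 0

    @property
    def end_s(self) -> float:
        """Nominal stimulus end: last pulse onset plus one period."""
        if self.is_empty:
            return 0.0
        return self.pulse_onsets_s[-1] + self.period_s


def make_pulse_protocol(scale: IntensityScale, n_blocks: int, isi_s: float,
                        pulse_width_ms: float = 10.0, *, seed: int) -> PulseProtocol:
    """Build a randomized-block intensity series.

    Each block contains every level of ``scale`` exactly once in an
    independent uniform random order; onsets are onset-to-onset spaced at
    ``isi_s`` starting from 0.  Block orders derive from per-block child seeds
    of ``seed`` so the whole design is reproducible and blocks are mutually
    independent.
    """
    if not isinstance(scale, IntensityScale) or scale.n_levels == 0:
        raise InvalidArgumentError("a valid IntensityScale is required")
    if n_blocks < 1:
        raise InvalidArgumentError("n_blocks must be >= 1")
    if isi_s <= 0:
        raise InvalidArgumentError("isi_s must be positive")
    if pulse_width_ms <= 0 or pulse_width_ms / 1000.0 >= isi_s:
        raise InvalidArgumentError("pulse width must be positive and shorter than the ISI")

    power = dict(zip(scale.levels, scale.power_mW))
    children = np.random.SeedSequence(seed).spawn(n_blocks)
    events: list[StimulusEvent] = []
    k = 0
    for b, child in enumerate(children):
        rng = np.random.default_rng(child)
        order = rng.permutation(np.asarray(scale.levels))
        for i, level in enumerate(order):
            events.append(
                StimulusEvent(
                    block_index=b,
                    within_block_index=i,
                    level=int(level),
                    power_mW=power[int(level)],
                    onset_s=k * isi_s,
                    pulse_width_ms=pulse_width_ms,
                )
            )
            k += 1
    return PulseProtocol(scale, n_blocks, float(isi_s), float(pulse_width_ms),
                         int(seed), tuple(events))


def make_train_protocol(frequency_hz: float, duration_s: float,
                        pulse_width_ms: float, power_mW: float = 0.0) -> TrainProtocol:
    """Build a fixed-frequency train.

    The pulse count is ``floor(duration_s * frequency_hz)`` complete periods
    with onsets at ``k / frequency_hz`` (6.67 Hz for 10 s -> 66 pulses).  An
    empty train (count 0) is returned with a warning rather than an error.
    """
    if frequency_hz <= 0:
        raise InvalidArgumentError("frequency_hz must be positive")
    if duration_s <= 0:
        raise InvalidArgumentError("duration_s must be positive")
    period = 1.0 / frequency_hz
    if pulse_width_ms <= 0 or pulse_width_ms / 1000.0 >= period:
        raise InvalidArgumentError("pulse width must be positive and shorter than the period")
    n = int(math.floor(duration_s * frequency_hz + 1e-9))
    if n == 0:
        warnings.warn("train contains zero complete periods (empty train)",
                      stacklevel=2)
    onsets = tuple(k * period for k in range(n))
    return TrainProtocol(float(frequency_hz), float(duration_s),
                         float(pulse_width_ms), float(power_mW), period, onsets)


def level_power_map(scale: IntensityScale, value: float, direction: str) -> float:
    """Convert between the linearized level scale and optical power.

    ``direction`` is ``"to_power"`` (level -> mW) or ``"to_level"``
    (mW -> level); both are piecewise-linear interpolations of the calibration
    table and are exact inverses within the calibrated range.
    """
    levels = np.asarray(scale.levels, dtype=float)
    power = np.asarray(scale.power_mW, dtype=float)
    v = float(value)
    if direction == "to_power":
        if v < levels[0] or v > levels[-1]:
            raise RangeError(f"level {v} outside calibrated range "
                             f"[{levels[0]}, {levels[-1]}]")
        return float(np.interp(v, levels, power))
    if direction == "to_level":
        if v < power[0] or v > power[-1]:
            raise RangeError(f"power {v} mW outside calibrated range "
                             f"[{power[0]}, {power[-1]}] mW")
        return float(np.interp(v, power, levels))
    raise InvalidArgumentError("direction must be 'to_power' or 'to_level'")


def write_protocol(protocol: PulseProtocol, csv_path, json_path=None) -> None:
    """Serialize a pulse protocol as a CSV event table plus a JSON header."""
    csv_path = str(csv_path)
    if json_path is None:
        json_path = csv_path[:-4] + ".json" if csv_path.endswith(".csv") else csv_path + ".json"
    protocol.to_frame().to_csv(csv_path, index=False)
    header = {
        "levels": list(protocol.scale.levels),
        "power_mW": list(protocol.scale.power_mW),
        "n_blocks": protocol.n_blocks,
        "isi_s": protocol.isi_s,
        "pulse_width_ms": protocol.pulse_width_ms,
        "seed": protocol.seed,
    }
    with open(json_path, "w") as fh:
        json.dump(header, fh, indent=1)


def read_protocol(csv_path, json_path=None) -> PulseProtocol:
    """Inverse of :func:`write_protocol`."""
    csv_path = str(csv_path)
    if json_path is None:
        json_path = csv_path[:-4] + ".json" if csv_path.endswith(".csv") else csv_path + ".json"
    with open(json_path) as fh:
        header = json.load(fh)
    table = pd.read_csv(csv_path, float_precision="round_trip")
    scale = IntensityScale(tuple(header["levels"]), tuple(header["power_mW"]))
    events = tuple(
        StimulusEvent(int(r.block), int(r.idx), int(r.level), float(r.power_mW),
                      float(r.onset_s), float(r.pulse_width_ms))
        for r in table.itertuples()
    )
    return PulseProtocol(scale, int(header["n_blocks"]), float(header["isi_s"]),
                         float(header["pulse_width_ms"]), int(header["seed"]), events)
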