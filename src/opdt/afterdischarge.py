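"""Afterdischarge-threshold staircase and kindling bookkeeping.

The afterdischarge threshold (ADT) is measured by presenting fixed-frequency
stimulus trains at ascending intensity until one evokes an afterdischarge;
the threshold is the first AD-evoking power and at most one AD is evoked per
session.  Kindling repeats the daily threshold procedure (with a fixed
per-animal ladder) and tracks threshold stability, behavioral (Racine) stage
progression, and the first day a stage-5 seizure appears.  Racine stages are
externally scored data, not computed here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .detect import ADResult
from .errors import InvalidArgumentError
from .protocol import TrainProtocol, make_train_protocol

__all__ = [
    "StaircaseConfig",
    "StaircaseStep",
    "StaircaseResult",
    "run_adt_staircase",
    "KindlingRecord",
    "KindlingSummary",
    "kindling_summary",
]


@dataclass(frozen=True)
class StaircaseConfig:
    """Ascending-intensity staircase design (defaults: 6.67 Hz, 10-s, 4-ms
    trains presented every 2 min)."""

    intensity_ladder: tuple[float, ...]
    inter_train_interval_s: float = 120.0
    max_steps: Optional[int] = None
    frequency_hz: float = 6.67
    duration_s: float = 10.0
    pulse_width_ms: float = 4.0

    def __post_init__(self) -> None:
        ladder = tuple(float(v) for v in self.intensity_ladder)
        object.__setattr__(self, "intensity_ladder", ladder)
        if not ladder:
            raise InvalidArgumentError("intensity ladder must be non-empty")
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise InvalidArgumentError("intensity ladder must be strictly increasing")


@dataclass(frozen=True)
class StaircaseStep:
    power_mW: float
    result: ADResult


@dataclass(frozen=True)
class StaircaseResult:
    """Outcome of one staircase session; ``threshold_mW`` is None when no AD
    was evoked at any presented intensity."""

    threshold_mW: Optional[float]
    steps: tuple[StaircaseStep, ...]

    @property
    def evoked_ad(self) -> bool:
        return self.threshold_mW is not None

    @property
    def n_steps(self) -> int:
        return len(self.steps)


def run_adt_staircase(config: StaircaseConfig,
                      respond: Callable[[TrainProtocol], ADResult]
                      ) -> StaircaseResult:
    """Ascend the intensity ladder until a train evokes an AD.

    ``respond`` maps a train protocol to an :class:`ADResult` (a recorded
    session, a simulator, or a deterministic oracle).  The staircase stops at
    the first AD — no further trains are presented — and the threshold is the
    AD-evoking power itself (the operational definition), not a midpoint.
    """
    if not callable(respond):
        raise InvalidArgumentError("respond must be callable")
    steps: list[StaircaseStep] = []
    ladder = config.intensity_ladder
    if config.max_steps is not None:
        ladder = ladder[:config.max_steps]
    for power in ladder:
        train = make_train_protocol(config.frequency_hz, config.duration_s,
                                    config.pulse_width_ms, power)
        result = respond(train)
        steps.append(StaircaseStep(power, result))
        if result.is_ad:
            return StaircaseResult(power, tuple(steps))
    return StaircaseResult(None, tuple(steps))


@dataclass(frozen=True)
class KindlingRecord:
    """One kindling day: threshold, AD duration, externally scored Racine
    stage (0-5; None when not scored)."""

    day: int
    adt_mW: float
    ad_duration_s: float
    racine_stage: Optional[int] = None

    def __post_init__(self) -> None:
        if self.racine_stage is not None and not (0 <= self.racine_stage <= 5):
            raise InvalidArgumentError("racine_stage must lie in 0..5")


@dataclass(frozen=True)
class KindlingSummary:
    threshold_day_rho: float
    threshold_day_p: float
    stage_day_rho: float
    stage_day_p: float
    days_to_stage5: Optional[int]
    n_days: int


def _spearman_perm(x: np.ndarray, y: np.ndarray, n_perm: int, seed: int
                   ) -> tuple[float, float]:
    """Spearman rho with a permutation p-value (exact for n <= 8)."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    rx = rankdata(x)
    ry = rankdata(y)

    def rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a * b).sum() / math.sqrt((a * a).sum() * (b * b).sum()))

    obs = rho(rx, ry)
    n = len(x)
    if math.factorial(n) <= 40320:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    ry_c = ry - ry.mean()
    rx_c = rx - rx.mean()
    denom = math.sqrt((rx_c * rx_c).sum() * (ry_c * ry_c).sum())
    stats = (rx_c[None, :] * ry_c[perms]).sum(axis=1) / denom
    p = float(np.mean(np.abs(stats) >= abs(obs) - 1e-12))
    return obs, p


def kindling_summary(records: Sequence[KindlingRecord], *, n_perm: int = 10000,
                     seed: int = 0) -> KindlingSummary:
    """Rank-correlation summary of a kindling series.

    Returns the Spearman correlation of threshold vs day (stability check:
    expected ~0), of Racine stage vs day (severity progression: expected
    positive), and the first day reaching stage 5.  Records with missing
    stages are excluded pairwise from the stage correlation.
    """
    if len(records) < 3:
        raise InvalidArgumentError("need >= 3 kindling records")
    days = np.array([r.day for r in records], dtype=float)
    thr = np.array([r.adt_mW for r in records], dtype=float)
    t_rho, t_p = _spearman_perm(days, thr, n_perm, seed)

    staged = [(r.day, r.racine_stage) for r in records if r.racine_stage is not None]
    if len(staged) >= 3:
        sd = np.array([d for d, _ in staged], dtype=float)
        ss = np.array([s for _, s in staged], dtype=float)
        s_rho, s_p = _spearman_perm(sd, ss, n_perm, seed + 1)
    else:
        s_rho, s_p = np.nan, np.nan

    stage5 = [r.day for r in records
              if r.racine_stage is not None and r.racine_stage >= 5]
    return KindlingSummary(t_rho, t_p, s_rho, s_p,
                           min(stage5) if stage5 else None, len(records))
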