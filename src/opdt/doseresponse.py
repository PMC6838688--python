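"""Intensity-response curves and Boltzmann I50 fitting.

The PD probability at stimulus intensity x is modelled with the
Hodgkin-Huxley form of the Boltzmann sigmoid

    f(x) = 1 / (1 + exp((a - x) / b)),

where ``a`` is the I50 (the intensity at which P(PD) = 0.5) and ``b`` the
slope.  Per-level PD ratios are fit by nonlinear least squares; uncertainty
comes from a block bootstrap because the randomized block is the exchangeable
design unit.  The module also produces binned I50 time courses and paired
condition comparisons (pharmacological shifts).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.special import expit

from .detect import DetectionResult
from .errors import InvalidArgumentError, NonIdentifiableError
from .protocol import PulseProtocol

__all__ = [
    "boltzmann",
    "ResponseCurve",
    "BoltzmannFit",
    "tabulate_ratios",
    "fit_boltzmann",
    "binned_i50",
    "ConditionComparison",
    "compare_conditions",
]


def boltzmann(x, a: float, b: float):
    """Boltzmann sigmoid f(x) = 1/(1 + exp((a - x)/b)); f(a) = 0.5 exactly."""
    if b == 0:
        raise InvalidArgumentError("slope b must be nonzero")
    return expit((np.asarray(x, dtype=float) - a) / b)


@dataclass
class ResponseCurve:
    """Per-level PD counts and ratios.

    ``block_table``/``block_totals`` (blocks x levels) preserve the design
    structure for the block bootstrap; they are attached automatically by
    :func:`tabulate_ratios`.
    """

    level: np.ndarray
    n_pd: np.ndarray
    n_total: np.ndarray
    power_mW: Optional[np.ndarray] = None
    block_table: Optional[np.ndarray] = None
    block_totals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.level = np.asarray(self.level, dtype=float)
        self.n_pd = np.asarray(self.n_pd)
        self.n_total = np.asarray(self.n_total)
        if not (len(self.level) == len(self.n_pd) == len(self.n_total)):
            raise InvalidArgumentError("level, n_pd, n_total must align")
        if np.any(self.n_total < 1):
            raise InvalidArgumentError("every included level needs >= 1 trial")
        if np.any(self.n_pd < 0) or np.any(self.n_pd > self.n_total):
            raise InvalidArgumentError("counts must satisfy 0 <= n_pd <= n_total")

    @property
    def ratio(self) -> np.ndarray:
        return self.n_pd / self.n_total

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"level": self.level, "n_pd": self.n_pd,
                            "n_total": self.n_total, "ratio": self.ratio})
        if self.power_mW is not None:
            out["power_mW"] = self.power_mW
        return out


@dataclass
class BoltzmannFit:
    """Fitted Boltzmann parameters with bootstrap uncertainty."""

    a: float                      # I50
    b: float                      # slope
    rss: float
    converged: bool
    axis: str = "level"
    ci_a: Optional[tuple[float, float]] = None
    ci_b: Optional[tuple[float, float]] = None
    n_boot: int = 0

    def f(self, x):
        """Evaluate the fitted sigmoid."""
        return boltzmann(x, self.a, self.b)

    def to_dict(self) -> dict:
        return {
            "a_i50": self.a, "b_slope": self.b, "rss": self.rss,
            "converged": self.converged, "axis": self.axis,
            "ci_a": list(self.ci_a) if self.ci_a else None,
            "ci_b": list(self.ci_b) if self.ci_b else None,
            "n_boot": self.n_boot,
        }


def tabulate_ratios(detections: DetectionResult, protocol: PulseProtocol
                    ) -> ResponseCurve:
    """Aggregate per-trial PD calls into per-level counts and ratios.

    Counts conserve the total number of trials; the per-block PD table is
    retained so fits can bootstrap over blocks.
    """
    events = detections.trial_events
    levels = np.array([e.level for e in events])
    blocks = np.array([e.block_index for e in events])
    is_pd = np.asarray(detections.is_pd, dtype=bool)
    if len(is_pd) != len(events):
        raise InvalidArgumentError("detections do not align with their events")

    uniq = np.array(sorted(set(protocol.scale.levels) | set(levels.tolist())))
    uniq = uniq[np.isin(uniq, levels)]  # only levels actually presented
    n_blocks = int(blocks.max()) + 1 if len(blocks) else 0
    table = np.zeros((n_blocks, len(uniq)), dtype=int)
    totals = np.zeros((n_blocks, len(uniq)), dtype=int)
    lvl_index = {int(l): j for j, l in enumerate(uniq)}
    for b, l, pd_ in zip(blocks, levels, is_pd):
        j = lvl_index[int(l)]
        table[b, j] += int(pd_)
        totals[b, j] += 1

    power = dict(zip(protocol.scale.levels, protocol.scale.power_mW))
    return ResponseCurve(
        level=uniq.astype(float),
        n_pd=table.sum(axis=0),
        n_total=totals.sum(axis=0),
        power_mW=np.array([power.get(int(l), np.nan) for l in uniq]),
        block_table=table,
        block_totals=totals,
    )


def _check_identifiable(ratio: np.ndarray) -> None:
    if not (np.any(ratio < 0.5) and np.any(ratio > 0.5)):
        raise NonIdentifiableError(
            "response curve needs observed ratios on both sides of 0.5 "
            f"(observed range [{ratio.min():.3f}, {ratio.max():.3f}])")


def _lsq_fit(x: np.ndarray, ratio: np.ndarray) -> tuple[float, float, float, bool]:
    a0 = float(x[np.argmin(np.abs(ratio - 0.5))])
    span = float(x.max() - x.min())
    lo = [x.min() - span / 2.0, 1e-6 * max(span, 1.0)]
    hi = [x.max() + span / 2.0, 2.0 * span]
    res = scipy.optimize.least_squares(
        lambda p: boltzmann(x, p[0], p[1]) - ratio,
        x0=[a0, min(max(1.0, lo[1] * 2), hi[1] * 0.5)],
        bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    a, b = float(res.x[0]), float(res.x[1])
    converged = bool(res.success) and b < hi[1] * 0.999
    return a, b, float(2.0 * res.cost), converged


def fit_boltzmann(curve: ResponseCurve, n_boot: int = 0, seed: int = 0,
                  axis: str = "level") -> BoltzmannFit:
    """Least-squares Boltzmann fit of a response curve.

    The fit minimizes sum((ratio - f(x))^2) with a initialized at the level
    whose ratio is nearest 0.5 and b at 1.  Curves without observed ratios on
    both sides of 0.5 (all-0, all-1, all-0.5) are non-identifiable and raise
    rather than extrapolate.  When ``n_boot`` > 0 the 95% CI comes from
    resampling whole blocks with replacement (requires the block table that
    :func:`tabulate_ratios` attaches).
    """
    if axis == "level":
        x = curve.level
    elif axis in ("power", "power_mW"):
        if curve.power_mW is None:
            raise InvalidArgumentError("curve has no power calibration")
        x = np.asarray(curve.power_mW, dtype=float)
    else:
        raise InvalidArgumentError("axis must be 'level' or 'power'")
    if len(x) < 4:
        raise InvalidArgumentError("need >= 4 levels for a well-posed fit")
    ratio = curve.ratio
    _check_identifiable(ratio)
    a, b, rss, converged = _lsq_fit(x, ratio)

    ci_a = ci_b = None
    if n_boot > 0:
        if curve.block_table is None or curve.block_totals is None:
            raise InvalidArgumentError(
                "block bootstrap requires the per-block table from tabulate_ratios")
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        n_blocks = curve.block_table.shape[0]
        boots_a, boots_b = [], []
        for _ in range(n_boot):
            pick = rng.integers(0, n_blocks, size=n_blocks)
            n_pd = curve.block_table[pick].sum(axis=0)
            n_tot = curve.block_totals[pick].sum(axis=0)
            ok = n_tot > 0
            r = n_pd[ok] / n_tot[ok]
            if not (np.any(r < 0.5) and np.any(r > 0.5)) or ok.sum() < 4:
                continue
            ab = _lsq_fit(x[ok], r)
            boots_a.append(ab[0])
            boots_b.append(ab[1])
        if len(boots_a) >= max(20, n_boot // 2):
            ci_a = tuple(np.percentile(boots_a, [2.5, 97.5]))
            ci_b = tuple(np.percentile(boots_b, [2.5, 97.5]))
    return BoltzmannFit(a, b, rss, converged, axis, ci_a, ci_b, n_boot)


def binned_i50(detections: DetectionResult, protocol: PulseProtocol,
               blocks_per_bin: int, axis: str = "level") -> pd.DataFrame:
    """I50 time course over consecutive bins of presentation blocks.

    Each bin spans ``blocks_per_bin * n_levels * isi`` seconds; the normalized
    series subtracts the whole-session I50.  Bins whose fit is
    non-identifiable carry NaN and ``converged=False`` (never interpolated).
    """
    if blocks_per_bin < 1:
        raise InvalidArgumentError("blocks_per_bin must be >= 1")
    n_bins = protocol.n_blocks // blocks_per_bin
    if n_bins < 1:
        raise InvalidArgumentError("not enough blocks for a single bin")

    session_fit = fit_boltzmann(tabulate_ratios(detections, protocol), axis=axis)
    blocks = np.array([e.block_index for e in detections.trial_events])
    span = blocks_per_bin * protocol.scale.n_levels * protocol.isi_s

    rows = []
    for k in range(n_bins):
        lo, hi = k * blocks_per_bin, (k + 1) * blocks_per_bin
        mask = (blocks >= lo) & (blocks < hi)
        sub = DetectionResult(
            max_rms=detections.max_rms[mask], threshold=detections.threshold,
            is_pd=detections.is_pd[mask], channel=detections.channel,
            search_window_s=detections.search_window_s,
            trial_events=tuple(e for e, m in zip(detections.trial_events, mask) if m),
        )
        i50, ok = np.nan, False
        try:
            f = fit_boltzmann(tabulate_ratios(sub, protocol), axis=axis)
            i50, ok = f.a, f.converged
        except NonIdentifiableError:
            pass
        rows.append({"bin_index": k, "bin_start_s": k * span,
                     "bin_end_s": (k + 1) * span, "i50": i50,
                     "i50_normalized": i50 - session_fit.a, "converged": ok})
    return pd.DataFrame(rows)


@dataclass
class ConditionComparison:
    """Paired condition shift: treatment I50 minus baseline I50 per subject
    (negative = leftward shift / increased excitability)."""

    per_subject: dict
    mean_shift: float
    ci: tuple[float, float]
    p_value: float
    n_pairs: int
    dropped: tuple = ()


def compare_conditions(i50s: pd.DataFrame, baseline: str = "baseline",
                       treatment: str = "treatment", *, n_boot: int = 2000,
                       seed: int = 0) -> ConditionComparison:
    """Paired I50 comparison across subjects.

    ``i50s`` has columns ``subject``, ``condition``, ``i50``; subjects missing
    either condition are excluded with a warning.  The p-value is an exact
    paired sign-flip permutation test on the mean shift (two-sided); the CI a
    subject-level bootstrap.
    """
    import warnings

    need = {"subject", "condition", "i50"}
    if not need.issubset(i50s.columns):
        raise InvalidArgumentError(f"i50s needs columns {sorted(need)}")
    wide = i50s.pivot_table(index="subject", columns="condition", values="i50",
                            aggfunc="mean")
    for cond in (baseline, treatment):
        if cond not in wide.columns:
            raise InvalidArgumentError(f"condition {cond!r} absent from data")
    paired = wide[[baseline, treatment]].dropna()
    dropped = tuple(wide.index.difference(paired.index))
    if dropped:
        warnings.warn(f"excluding unpaired subjects: {list(dropped)}",
                      stacklevel=2)
    if len(paired) < 2:
        raise InvalidArgumentError("need >= 2 subjects with both conditions")

    diffs = (paired[treatment] - paired[baseline]).to_numpy()
    n = len(diffs)
    observed = float(diffs.mean())

    # exact sign-flip permutation (2^n flips for n <= 20, else Monte Carlo)
    if n <= 20:
        signs = np.array(list(itertools.product([-1.0, 1.0], repeat=n)))
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        signs = rng.choice([-1.0, 1.0], size=(100_000, n))
    perm_means = (signs * diffs).mean(axis=1)
    p = float(np.mean(np.abs(perm_means) >= abs(observed) - 1e-12))

    rng = np.random.default_rng(np.random.SeedSequence(seed + 1))
    boots = np.array([diffs[rng.integers(0, n, n)].mean() for _ in range(n_boot)])
    ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return ConditionComparison(dict(zip(paired.index, diffs)), observed, ci,
                               p, n, dropped)
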