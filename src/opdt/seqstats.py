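"""Trial-history and train-level conditional-probability statistics.

Conditional probabilities are computed as exact relative frequencies and are
always returned with their numerator and denominator; an empty conditioning
set raises (never a silent 0/0).  Proportions are compared with Fisher's
exact test (two-sided, probability-mass convention) and families of tests are
corrected with the Holm-Sidak step-down procedure.  ``n-back`` counts
stimulus events, not seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import InvalidArgumentError, UndefinedProbabilityError

__all__ = [
    "TrialSequence",
    "TrainOutcome",
    "ConditionalProbability",
    "NBackConditional",
    "p_ad_given_cum_pds",
    "p_ad_given_pd_on_pulse",
    "p_pd_at_i50_given_nback",
    "nback_suppression_table",
    "fisher_exact",
    "holm_sidak",
    "nback_amplitude_profile",
    "AmplitudeProfile",
]


@dataclass
class TrialSequence:
    """Ordered single-pulse trials: (time, level, PD call, evoked amplitude)."""

    time_s: np.ndarray
    level: np.ndarray
    is_pd: np.ndarray
    amplitude: Optional[np.ndarray] = None
    isi_s: Optional[float] = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.level = np.asarray(self.level, dtype=float)
        self.is_pd = np.asarray(self.is_pd, dtype=bool)
        if self.amplitude is not None:
            self.amplitude = np.asarray(self.amplitude, dtype=float)
            if len(self.amplitude) != len(self.time_s):
                raise InvalidArgumentError("amplitude must align with trials")
        if not (len(self.time_s) == len(self.level) == len(self.is_pd)):
            raise InvalidArgumentError("trial arrays must align")
        if np.any(np.diff(self.time_s) <= 0):
            raise InvalidArgumentError("trial times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time_s)


@dataclass
class TrainOutcome:
    """One stimulus train: intensity, per-pulse PD vector, AD indicator."""

    power_mW: float
    pulse_pd: np.ndarray
    is_ad: bool

    def __post_init__(self) -> None:
        self.pulse_pd = np.asarray(self.pulse_pd, dtype=bool)

    @property
    def pd_count(self) -> int:
        return int(np.count_nonzero(self.pulse_pd))


@dataclass(frozen=True)
class ConditionalProbability:
    estimate: float
    numerator: int
    denominator: int


@dataclass(frozen=True)
class NBackConditional:
    """P(PD at ~I50 | PD n trials back) with its marginal reference."""

    estimate: float
    numerator: int
    denominator: int
    marginal: float
    marginal_n: int
    n_back: int


def p_ad_given_cum_pds(trains: Sequence[TrainOutcome], x: int
                       ) -> ConditionalProbability:
    """P(AD | sum of PDs in the train >= x)."""
    denom = [t for t in trains if t.pd_count >= x]
    if not denom:
        raise UndefinedProbabilityError(
            f"no train with >= {x} PDs; conditional undefined")
    num = sum(t.is_ad for t in denom)
    return ConditionalProbability(num / len(denom), int(num), len(denom))


def p_ad_given_pd_on_pulse(trains: Sequence[TrainOutcome], n: int
                           ) -> ConditionalProbability:
    """P(AD | PD on pulse n), n a 0-based pulse index present in every train."""
    if any(n >= len(t.pulse_pd) or n < 0 for t in trains):
        raise InvalidArgumentError(f"pulse index {n} not present in all trains")
    denom = [t for t in trains if t.pulse_pd[n]]
    if not denom:
        raise UndefinedProbabilityError(
            f"no train with a PD on pulse {n}; conditional undefined")
    num = sum(t.is_ad for t in denom)
    return ConditionalProbability(num / len(denom), int(num), len(denom))


def _i50_trials(seq: TrialSequence, i50: float, tol: float) -> np.ndarray:
    if tol <= 0:
        raise InvalidArgumentError("tol must be positive")
    return np.abs(seq.level - i50) <= tol


def p_pd_at_i50_given_nback(seq: TrialSequence, i50: float, tol: float = 0.25,
                            n_back: int = 1) -> NBackConditional:
    """P(PD at a level within +-tol of the I50 | PD on the n-back trial).

    The conditioning trials are those near the I50 whose n-back trial (at any
    level) produced a PD; the marginal is P(PD) over all near-I50 trials.
    Each n is computed independently of the others.
    """
    if n_back < 1:
        raise InvalidArgumentError("n_back must be >= 1")
    sel = _i50_trials(seq, i50, tol)
    marginal_n = int(sel.sum())
    if marginal_n == 0:
        raise UndefinedProbabilityError("no trials within tol of the I50")
    marginal = float(seq.is_pd[sel].mean())
    idx = np.flatnonzero(sel)
    idx = idx[idx >= n_back]
    cond = idx[seq.is_pd[idx - n_back]]
    if cond.size == 0:
        raise UndefinedProbabilityError(
            f"no near-I50 trial preceded by a PD at {n_back}-back")
    num = int(seq.is_pd[cond].sum())
    return NBackConditional(num / cond.size, num, int(cond.size),
                            marginal, marginal_n, n_back)


def nback_suppression_table(seqs: Sequence[TrialSequence],
                            i50s: Sequence[float], tol: float = 0.25,
                            n_backs: Sequence[int] = (1, 2, 3)) -> pd.DataFrame:
    """Pooled n-back PD-suppression analysis across sessions.

    For each n, near-I50 trials (pooled over sessions, trial-weighted) are
    split by whether their n-back trial produced a PD; the two proportions are
    compared with Fisher's exact test and the family of n values is
    Holm-Sidak corrected.
    """
    if len(seqs) != len(i50s):
        raise InvalidArgumentError("one i50 per session required")
    rows = []
    for n in n_backs:
        pd_prev = np.zeros(2, dtype=int)    # [PD, no-PD] given prev PD
        pd_noprev = np.zeros(2, dtype=int)  # given prev no-PD
        for seq, i50 in zip(seqs, i50s):
            sel = np.flatnonzero(_i50_trials(seq, i50, tol))
            sel = sel[sel >= n]
            prev = seq.is_pd[sel - n]
            cur = seq.is_pd[sel]
            pd_prev += [int((cur & prev).sum()), int((~cur & prev).sum())]
            pd_noprev += [int((cur & ~prev).sum()), int((~cur & ~prev).sum())]
        table = np.array([pd_prev, pd_noprev])
        denom_prev = pd_prev.sum()
        if denom_prev == 0:
            raise UndefinedProbabilityError(
                f"no near-I50 trial preceded by a PD at {n}-back")
        rows.append({
            "n_back": n,
            "p_pd_given_prev_pd": pd_prev[0] / denom_prev,
            "n_prev_pd": int(denom_prev),
            "p_pd_given_prev_no_pd": (pd_noprev[0] / pd_noprev.sum()
                                      if pd_noprev.sum() else np.nan),
            "n_prev_no_pd": int(pd_noprev.sum()),
            "p_raw": fisher_exact(table),
        })
    out = pd.DataFrame(rows)
    out["p_adjusted"] = holm_sidak(out["p_raw"].to_numpy())
    return out


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact test for a 2x2 table of counts.

    Probability-mass convention: sum the hypergeometric probabilities of all
    tables with the same margins whose probability is at most that of the
    observed table (with 1e-7 relative slack for floating-point ties).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InvalidArgumentError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t != np.floor(t)) or np.any(t < 0):
            raise InvalidArgumentError("counts must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        raise InvalidArgumentError("all margins must be positive")
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def holm_sidak(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in the input order.

    Sort ascending, set adjusted_(i) = 1 - (1 - p_(i))**(m - i + 1), enforce
    monotone non-decreasing adjusted values, and cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj = np.minimum(np.maximum.accumulate(adj), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class AmplitudeProfile:
    """Mean normalized evoked amplitude at a probe level, grouped by the
    level of the immediately preceding stimulus."""

    prev_level: np.ndarray
    mean_amplitude: np.ndarray
    counts: np.ndarray
    slope: float


def nback_amplitude_profile(seqs, probe_level: float) -> AmplitudeProfile:
    """Desensitization profile: response amplitude at ``probe_level`` as a
    function of the 1-back stimulus level.

    Amplitudes are min-max normalized per session (min -> 0, max -> 1), probe
    trials grouped by the preceding level, and a least-squares slope fit over
    the group means.  Sparse or empty cells are reported through ``counts``
    and excluded from the slope.
    """
    if isinstance(seqs, TrialSequence):
        seqs = [seqs]
    groups: dict[float, list[float]] = {}
    for seq in seqs:
        if seq.amplitude is None:
            raise InvalidArgumentError("sequence has no amplitude data")
        amp = seq.amplitude
        lo, hi = amp.min(), amp.max()
        if hi == lo:
            raise InvalidArgumentError("degenerate amplitudes; cannot normalize")
        norm = (amp - lo) / (hi - lo)
        probe = np.flatnonzero(seq.level == probe_level)
        probe = probe[probe >= 1]
        for i in probe:
            groups.setdefault(float(seq.level[i - 1]), []).append(float(norm[i]))
    if not groups:
        raise InvalidArgumentError(
            f"probe level {probe_level} never follows another stimulus")
    prev = np.array(sorted(groups))
    means = np.array([np.mean(groups[l]) for l in prev])
    counts = np.array([len(groups[l]) for l in prev])
    if len(prev) >= 2:
        slope = float(np.polyfit(prev, means, 1)[0])
    else:
        slope = np.nan
    return AmplitudeProfile(prev, means, counts, slope)
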