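"""Population-discharge and afterdischarge detection.

The PD detector follows a fixed pipeline: band-limit the trace (5-300 Hz,
zero phase), extract peri-stimulus epochs, take the discrete second
derivative, smooth with a short sliding-RMS window, and reduce each trial to
the maximum RMS inside a post-onset search window.  Because the PD is
all-or-none, the per-trial statistics are bimodal; the detection threshold is
placed in the largest gap of the sorted statistics and every statistic above
it is called a PD.  Afterdischarges are detected from the band-limited
envelope after the end of a stimulus train (sustained supra-baseline activity
for at least 5 s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.signal

from .errors import InvalidArgumentError, NoSeparationError
from .protocol import PulseProtocol, StimulusEvent, TrainProtocol
from .synth import Session

__all__ = [
    "EpochSet",
    "DetectionResult",
    "ADResult",
    "ThresholdSuggestion",
    "bandpass",
    "extract_epochs",
    "second_derivative",
    "sliding_rms",
    "max_rms_statistic",
    "sorted_peak_curve",
    "suggest_threshold",
    "select_channel",
    "detect_pds",
    "measure_evoked_amplitude",
    "detect_afterdischarge",
]


@dataclass
class EpochSet:
    """Stimulus-aligned trial matrix (sample ``onset_index`` is the onset)."""

    data: np.ndarray                      # (n_trials, n_samples)
    window_s: tuple[float, float]         # (pre, post), both positive
    fs_hz: float
    trial_events: tuple[StimulusEvent, ...]
    excluded: tuple[int, ...] = ()        # event indices clipped at the edges

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def onset_index(self) -> int:
        return int(round(self.window_s[0] * self.fs_hz))


@dataclass
class DetectionResult:
    """Per-trial max-RMS statistics with the threshold and binary PD calls."""

    max_rms: np.ndarray
    threshold: float
    is_pd: np.ndarray
    channel: str
    search_window_s: tuple[float, float]
    trial_events: tuple[StimulusEvent, ...]
    separation: Optional[float] = None
    excluded: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.max_rms) != len(self.trial_events):
            raise InvalidArgumentError("max_rms must align with trial_events")
        if not np.array_equal(self.is_pd, self.max_rms > self.threshold):
            raise InvalidArgumentError("is_pd must equal (max_rms > threshold)")

    @property
    def n_trials(self) -> int:
        return len(self.max_rms)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "block": [e.block_index for e in self.trial_events],
                "level": [e.level for e in self.trial_events],
                "power_mW": [e.power_mW for e in self.trial_events],
                "onset_s": [e.onset_s for e in self.trial_events],
                "max_rms": self.max_rms,
                "is_pd": self.is_pd.astype(int),
            }
        )


@dataclass
class ADResult:
    """Outcome of afterdischarge detection for one stimulus train."""

    is_ad: bool
    duration_s: float          # train start to last supra-baseline spike
    envelope_exceed_s: float   # sustained supra-baseline time after train end

    def __post_init__(self) -> None:
        if self.is_ad and self.envelope_exceed_s < 5.0:
            raise InvalidArgumentError(
                "is_ad requires >= 5 s of sustained post-train activity")


@dataclass(frozen=True)
class ThresholdSuggestion:
    threshold: float
    separation: float   # gap width / interquartile range
    gap: float


def bandpass(x: np.ndarray, fs_hz: float, lo_hz: float = 5.0,
             hi_hz: float = 300.0, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass with -3 dB at the band edges.

    Forward-backward filtering squares the magnitude response, so each corner
    is pre-warped (in the bilinear tan domain, by a factor of
    ``(sqrt(2)-1)**(1/(2*order))``) to leave the two-pass response at -3 dB at
    ``lo_hz`` and ``hi_hz``.  High- and low-pass sections are designed
    separately so the corners do not interact.
    """
    shift = (np.sqrt(2.0) - 1.0) ** (1.0 / (2.0 * order))

    def warp(f_hz: float, factor: float) -> float:
        t = np.tan(np.pi * f_hz / fs_hz) * factor
        return float(np.arctan(t) * fs_hz / np.pi)

    lo = warp(lo_hz, shift)
    hi = min(warp(hi_hz, 1.0 / shift), 0.499 * fs_hz)
    sos = np.vstack([
        scipy.signal.butter(order, lo, btype="highpass", fs=fs_hz, output="sos"),
        scipy.signal.butter(order, hi, btype="lowpass", fs=fs_hz, output="sos"),
    ])
    return scipy.signal.sosfiltfilt(sos, x, axis=-1)


def extract_epochs(session: Session, channel: str, pre_s: float = 0.05,
                   post_s: float = 0.15, *, band: Optional[tuple] = (5.0, 300.0)
                   ) -> EpochSet:
    """Cut stimulus-aligned epochs from one channel.

    The continuous trace is band-limited first (pass ``band=None`` to skip).
    Events too close to the recording edges are excluded with a warning and
    recorded in ``EpochSet.excluded``; alignment is exact to the nearest
    sample.
    """
    if pre_s < 0 or post_s <= 0:
        raise InvalidArgumentError("pre_s must be >= 0 and post_s > 0")
    trace = session.channel(channel)
    if band is not None:
        trace = bandpass(trace, session.fs_hz, band[0], band[1])
    fs = session.fs_hz
    n_pre = int(round(pre_s * fs))
    n_post = int(round(post_s * fs))
    rows, kept, excluded = [], [], []
    for i, ev in enumerate(session.events):
        i0 = int(round(ev.onset_s * fs))
        if i0 - n_pre < 0 or i0 + n_post > trace.shape[0]:
            excluded.append(i)
            continue
        rows.append(trace[i0 - n_pre:i0 + n_post])
        kept.append(i)
    if excluded:
        warnings.warn(f"excluded {len(excluded)} edge-clipped trial(s): "
                      f"{excluded}", stacklevel=2)
    data = np.asarray(rows, dtype=float) if rows else np.empty((0, n_pre + n_post))
    return EpochSet(data, (pre_s, post_s), fs,
                    tuple(session.events[i] for i in kept), tuple(excluded))


def second_derivative(trace: np.ndarray, fs_hz: float) -> np.ndarray:
    """Discrete second derivative (central second difference x fs^2).

    The output has the same length as the input; the two edge samples
    replicate their nearest interior value.  Exact for quadratics away from
    the edges, and invariant to any additive constant or linear trend.
    """
    x = np.asarray(trace, dtype=float)
    if x.shape[-1] < 5:
        raise InvalidArgumentError("trace must have at least 5 samples")
    out = np.empty_like(x)
    out[..., 1:-1] = (x[..., 2:] - 2.0 * x[..., 1:-1] + x[..., :-2]) * fs_hz ** 2
    out[..., 0] = out[..., 1]
    out[..., -1] = out[..., -2]
    return out


def sliding_rms(trace: np.ndarray, window_ms: float, fs_hz: float) -> np.ndarray:
    """Centered sliding-window RMS (window forced to an odd sample count).

    Edge windows average only the available samples, so the output length
    equals the input length and a constant input maps to its absolute value.
    """
    n = int(round(window_ms / 1000.0 * fs_hz))
    n = max(n, 1)
    if n % 2 == 0:
        n += 1
    x = np.asarray(trace, dtype=float)
    kernel = np.ones(n)
    sq = scipy.ndimage.convolve1d(x * x, kernel, axis=-1, mode="constant", cval=0.0)
    counts = scipy.ndimage.convolve1d(np.ones(x.shape[-1]), kernel,
                                      mode="constant", cval=0.0)
    return np.sqrt(np.maximum(sq / counts, 0.0))


def max_rms_statistic(epochs: EpochSet, search_window_s: tuple[float, float] =
                      (0.005, 0.100), *, rms_window_ms: float = 10.0) -> np.ndarray:
    """Per-trial detection statistic: max sliding-RMS of the 2nd derivative
    inside a post-onset search window."""
    start, end = search_window_s
    if not (0.0 <= start < end <= epochs.window_s[1]):
        raise InvalidArgumentError(
            f"search window {search_window_s} must lie within "
            f"(0, {epochs.window_s[1]}] s post-onset")
    if epochs.n_trials == 0:
        return np.empty(0)
    d2 = second_derivative(epochs.data, epochs.fs_hz)
    rms = sliding_rms(d2, rms_window_ms, epochs.fs_hz)
    i0 = epochs.onset_index
    a = i0 + int(round(start * epochs.fs_hz))
    b = i0 + int(round(end * epochs.fs_hz))
    if b <= a:
        raise InvalidArgumentError("empty search window")
    return rms[:, a:b].max(axis=1)


def sorted_peak_curve(stats: np.ndarray, events: Sequence[StimulusEvent]
                      ) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Descending-sorted statistics per level plus the pooled sorted array
    (the visualization used to place the threshold)."""
    stats = np.asarray(stats, dtype=float)
    if len(stats) != len(events):
        raise InvalidArgumentError("stats must align with events")
    per_level: dict[int, np.ndarray] = {}
    levels = np.array([e.level for e in events])
    for lvl in np.unique(levels):
        per_level[int(lvl)] = np.sort(stats[levels == lvl])[::-1]
    return per_level, np.sort(stats)[::-1]


def suggest_threshold(stats: np.ndarray) -> ThresholdSuggestion:
    """Automatic threshold: midpoint of the largest gap between consecutive
    sorted statistics, restricted to the inner 5-95% quantile range.

    The separation score is the gap width divided by the interquartile range;
    any manual threshold always overrides this suggestion downstream.
    """
    s = np.sort(np.asarray(stats, dtype=float))
    if s.size < 4:
        raise InvalidArgumentError("need at least 4 trials to set a threshold")
    if s[0] == s[-1]:
        raise NoSeparationError("all statistics identical; no sub/supra gap")
    q5, q25, q75, q95 = np.quantile(s, [0.05, 0.25, 0.75, 0.95])
    inner = s[(s >= q5) & (s <= q95)]
    if inner.size < 2:
        inner = s
    gaps = np.diff(inner)
    i = int(np.argmax(gaps))
    gap = float(gaps[i])
    if gap == 0.0:
        raise NoSeparationError("no gap between sorted statistics")
    iqr = q75 - q25
    denom = iqr if iqr > 0 else (s[-1] - s[0]) * 1e-12
    return ThresholdSuggestion(float((inner[i] + inner[i + 1]) / 2.0),
                               gap / denom, gap)


def select_channel(session: Session, candidates: Optional[Sequence[str]] = None,
                   protocol: Optional[PulseProtocol] = None, *,
                   pre_s: float = 0.05, post_s: float = 0.15,
                   search_window_s: tuple[float, float] = (0.005, 0.100)
                   ) -> tuple[str, dict[str, float]]:
    """Pick the channel with the sharpest sub/supra-threshold transition.

    Each candidate is scored by the separation score of its automatic
    threshold; ties break in candidate order.  If no candidate separates, a
    :class:`NoSeparationError` lists all scores.
    """
    candidates = list(candidates) if candidates else list(session.channel_names)
    if not candidates:
        raise InvalidArgumentError("at least one candidate channel required")
    scores: dict[str, float] = {}
    for name in candidates:
        try:
            epochs = extract_epochs(session, name, pre_s, post_s)
            stats = max_rms_statistic(epochs, search_window_s)
            scores[name] = suggest_threshold(stats).separation
        except (NoSeparationError, InvalidArgumentError):
            scores[name] = float("-inf")
    best = max(candidates, key=lambda c: scores[c])  # max() keeps first on ties
    if not np.isfinite(scores[best]):
        raise NoSeparationError(f"no candidate channel separates; scores: {scores}")
    return best, scores


def detect_pds(session: Session, channel: Optional[str] = None, *,
               pre_s: float = 0.05, post_s: float = 0.15,
               search_window_s: tuple[float, float] = (0.005, 0.100),
               rms_window_ms: float = 10.0,
               threshold: Optional[float] = None) -> DetectionResult:
    """Full PD detection on one session.

    ``channel=None`` selects the best-separating channel automatically;
    ``threshold=None`` uses the automatic largest-gap threshold, otherwise the
    given manual threshold is honored as-is.
    """
    if channel is None:
        channel, _ = select_channel(session, pre_s=pre_s, post_s=post_s,
                                    search_window_s=search_window_s)
    epochs = extract_epochs(session, channel, pre_s, post_s)
    stats = max_rms_statistic(epochs, search_window_s,
                              rms_window_ms=rms_window_ms)
    separation = None
    if threshold is None:
        suggestion = suggest_threshold(stats)
        threshold = suggestion.threshold
        separation = suggestion.separation
    return DetectionResult(
        max_rms=stats, threshold=float(threshold),
        is_pd=stats > threshold, channel=channel,
        search_window_s=search_window_s, trial_events=epochs.trial_events,
        separation=separation, excluded=epochs.excluded,
    )


def measure_evoked_amplitude(session: Session, channel: str,
                             window_s: tuple[float, float] = (0.0, 0.03)
                             ) -> np.ndarray:
    """Peak absolute band-limited deflection after each stimulus (µV); used
    for the desensitization (n-back amplitude) analysis at the stim site."""
    epochs = extract_epochs(session, channel, pre_s=0.05,
                            post_s=max(window_s[1], 0.05))
    i0 = epochs.onset_index
    a = i0 + int(round(window_s[0] * epochs.fs_hz))
    b = i0 + int(round(window_s[1] * epochs.fs_hz))
    return np.abs(epochs.data[:, a:b]).max(axis=1)


def _supra_spans(mask: np.ndarray, fs: float, gap_tol_s: float
                 ) -> list[tuple[int, int]]:
    """Runs of True in ``mask``, with gaps <= gap_tol_s merged."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    gap = int(round(gap_tol_s * fs))
    spans = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > gap:
            spans.append((start, prev))
            start = i
        prev = i
    spans.append((start, prev))
    return spans


def detect_afterdischarge(session: Session, train: TrainProtocol,
                          channel: str, *, k_baseline: float = 4.0,
                          spike_sd_mult: float = 5.0,
                          rms_window_ms: float = 100.0,
                          search_s: float = 35.0, min_supra_s: float = 5.0,
                          gap_tol_s: float = 0.5) -> ADResult:
    """Afterdischarge detection after a stimulus train.

    The 5-300 Hz envelope (100-ms sliding RMS) must exceed ``k_baseline``
    times the pre-stimulus baseline median for at least ``min_supra_s``
    cumulative seconds (gaps up to ``gap_tol_s`` tolerated) within
    ``search_s`` of the train end.  Duration runs from the train start to the
    last supra-baseline spike (|x| > ``spike_sd_mult`` baseline SDs).
    """
    if not session.events:
        raise InvalidArgumentError("session has no stimulus events")
    fs = session.fs_hz
    t0 = session.events[0].onset_s
    t_end = session.events[-1].onset_s + train.period_s
    if session.duration_s < t_end + search_s:
        raise InvalidArgumentError(
            f"session must cover >= {search_s} s after the train end "
            f"({t_end + search_s:.1f} s needed, {session.duration_s:.1f} s present)")
    x = bandpass(session.channel(channel), fs)
    env = sliding_rms(x, rms_window_ms, fs)

    b0 = int(round(max(0.0, t0 - 5.0) * fs))
    b1 = int(round((t0 - 0.1) * fs))
    if b1 - b0 < int(fs):
        raise InvalidArgumentError("need >= 1 s of pre-stimulus baseline")
    baseline_med = float(np.median(env[b0:b1]))
    baseline_sd = float(np.std(x[b0:b1]))

    p0 = int(round(t_end * fs))
    p1 = int(round((t_end + search_s) * fs))
    supra = env[p0:p1] > k_baseline * baseline_med
    spans = _supra_spans(supra, fs, gap_tol_s)
    exceed_s = sum((b - a + 1) for a, b in spans) / fs
    is_ad = exceed_s >= min_supra_s

    duration = 0.0
    spikes = np.flatnonzero(np.abs(x[int(round(t0 * fs)):p1])
                            > spike_sd_mult * baseline_sd)
    if spikes.size:
        duration = spikes[-1] / fs
    return ADResult(bool(is_ad), float(duration), float(exceed_s))
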