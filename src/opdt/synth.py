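"""Ground-truth-labelled synthetic LFP sessions.

The generator emulates the statistical structure the threshold procedure
assumes: an all-or-none network population discharge (PD) whose probability
follows a Boltzmann sigmoid of stimulus intensity, a graded short-latency
evoked response at the stimulation site, channelrhodopsin desensitization
(history-dependent evoked amplitude), post-PD suppression of PD probability
inside a short window, 1/f background noise, spontaneous interictal spikes,
and — for train stimuli — afterdischarges whose probability accumulates with
the number of PDs evoked by the train.

Every simulated trial carries its ground-truth label so the detection and
fitting stages can be scored exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import scipy.fft

from .errors import InvalidArgumentError
from .protocol import (IntensityScale, PulseProtocol, StimulusEvent,
                       TrainProtocol)

__all__ = [
    "GroundTruthModel",
    "ADAccumulationModel",
    "Session",
    "PulseOutcomes",
    "TrainDraw",
    "channel_layout",
    "powerlaw_noise",
    "pd_template",
    "draw_pulse_outcomes",
    "simulate_pulse_session",
    "draw_train_outcome",
    "simulate_train_session",
    "inject_spontaneous_iis",
    "SCENARIOS",
    "scenario_model",
    "make_scenario_session",
]

# Channel layout of the chronic 8-wire array; the optrode (stimulation site)
# is right CA1 and carries the graded evoked response.  Downstream sites carry
# the all-or-none PD with site-dependent gain; contralateral CA1 shows the
# sharpest sub/supra separation.
_NAMES_8 = ("PFC", "AMTh", "DG", "CA3", "Ent", "Sub", "CA1-L", "CA1-R")
_PD_GAIN_8 = (0.15, 0.25, 0.90, 0.85, 0.45, 0.60, 1.00, 0.00)
_STIM_8 = "CA1-R"


def channel_layout(n_channels: int) -> tuple[tuple[str, ...], str, np.ndarray]:
    """Return (channel names, stimulation-channel name, per-channel PD gain)."""
    if n_channels < 2:
        raise InvalidArgumentError("at least 2 channels required (stim + downstream)")
    if n_channels == 8:
        return _NAMES_8, _STIM_8, np.array(_PD_GAIN_8)
    names = tuple(f"ds{i}" for i in range(n_channels - 1)) + ("stim",)
    gains = np.concatenate([np.linspace(0.3, 1.0, n_channels - 1)[::-1], [0.0]])
    return names, "stim", gains


@dataclass(frozen=True)
class GroundTruthModel:
    """Generating parameters of a synthetic session.

    ``a_true``/``b_true`` are the Boltzmann I50 and slope (level units) of the
    true PD probability curve.  ``suppress_rho`` multiplies PD probability when
    the preceding PD trial started less than ``suppress_window_s`` before the
    current stimulus (onset-to-onset).  Desensitization reduces the evoked
    amplitude by ``desens_delta`` per unit of recent stimulus level, recovering
    exponentially with ``desens_tau_s``.
    """

    a_true: float = 16.4          # I50, level units
    b_true: float = 1.5           # slope, level units
    evoked_gain: float = 8.0      # µV per level at the stimulation site
    pd_amplitude: float = 400.0   # µV, network PD waveform
    pd_latency_ms: float = 10.0   # network latency of the PD
    noise_sd: float = 6.0         # µV RMS of 1/f background
    noise_exponent: float = 1.0   # spectral slope of background noise
    desens_delta: float = 0.005   # fractional amplitude loss per level unit
    desens_tau_s: float = 5.0     # desensitization recovery time constant
    suppress_rho: float = 0.5     # multiplicative P(PD) factor after a PD
    suppress_window_s: float = 2.0
    n_channels: int = 8
    fs_hz: float = 2000.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.suppress_rho <= 1.0):
            raise InvalidArgumentError("suppress_rho must lie in [0, 1]")
        if self.b_true <= 0:
            raise InvalidArgumentError("b_true must be positive")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be non-negative")
        if self.pd_latency_ms <= 0:
            raise InvalidArgumentError("pd_latency_ms must be positive")

    def p_pd(self, level) -> np.ndarray:
        """True PD probability at a given level (no history effects)."""
        x = np.asarray(level, dtype=float)
        return 1.0 / (1.0 + np.exp((self.a_true - x) / self.b_true))


@dataclass(frozen=True)
class ADAccumulationModel:
    """Afterdischarge probability as a function of accumulated PDs.

    P(AD | n PDs) = logistic(k_steepness * (n - p50_pds)) for n >= 1 and 0 for
    n = 0 (an AD requires at least one PD).  The defaults give P(AD) ~= 0.92
    at 8 PDs and > 0.99 at 17 PDs.  Within a train the per-pulse PD
    probability decays geometrically by ``desens_pulse_decay``.
    """

    p50_pds: float = 5.0
    k_steepness: float = 0.8
    desens_pulse_decay: float = 0.97

    def __post_init__(self) -> None:
        if self.p50_pds <= 0 or self.k_steepness <= 0:
            raise InvalidArgumentError("p50_pds and k_steepness must be positive")
        if not (0.0 < self.desens_pulse_decay <= 1.0):
            raise InvalidArgumentError("desens_pulse_decay must lie in (0, 1]")

    def p_ad(self, n_pds: int) -> float:
        if n_pds <= 0:
            return 0.0
        return 1.0 / (1.0 + math.exp(-self.k_steepness * (n_pds - self.p50_pds)))


@dataclass
class Session:
    """A continuous multi-channel recording with its stimulus event table.

    ``truth_pd`` / ``truth_ad`` are present for simulated data only and align
    1:1 with ``events`` (per-pulse for trains).
    """

    lfp: np.ndarray                     # (channels, samples) float32, µV
    fs_hz: float
    events: tuple[StimulusEvent, ...]
    channel_names: tuple[str, ...]
    truth_pd: Optional[np.ndarray] = None
    truth_ad: Optional[bool] = None
    iis_times: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lfp.ndim != 2 or self.lfp.shape[0] != len(self.channel_names):
            raise InvalidArgumentError("lfp must be (n_channels, n_samples)")
        span = self.lfp.shape[1] / self.fs_hz
        for e in self.events:
            if not (0.0 <= e.onset_s < span):
                raise InvalidArgumentError(
                    f"event onset {e.onset_s}s outside recording span {span}s")
        if self.truth_pd is not None and len(self.truth_pd) != len(self.events):
            raise InvalidArgumentError("truth_pd must align 1:1 with events")

    @property
    def duration_s(self) -> float:
        return self.lfp.shape[1] / self.fs_hz

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channel_names:
            raise InvalidArgumentError(
                f"unknown channel {name!r}; available: {list(self.channel_names)}")
        return self.lfp[self.channel_names.index(name)]


@dataclass(frozen=True)
class PulseOutcomes:
    """Per-trial ground truth drawn before waveform rendering."""

    is_pd: np.ndarray          # bool
    amplitude: np.ndarray      # evoked amplitude at the stim site, µV
    p: np.ndarray              # realized PD probability (incl. suppression)
    desens_factor: np.ndarray  # evoked amplitude multiplier in [0, 1]


@dataclass(frozen=True)
class TrainDraw:
    """Ground truth of one simulated stimulus train."""

    power_mW: float
    pulse_pd: np.ndarray       # bool, one entry per pulse
    is_ad: bool
    ad_duration_s: float       # from train start to last spike; 0 when no AD

    @property
    def pd_count(self) -> int:
        return int(np.count_nonzero(self.pulse_pd))


def powerlaw_noise(n_channels: int, n_samples: int, exponent: float, sd: float,
                   fs_hz: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise shaped to a 1/f**exponent amplitude spectrum.

    Spectral synthesis: draw a complex Gaussian spectrum, weight by
    f**(-exponent/2), inverse-transform, and rescale each channel to ``sd``.
    """
    if sd == 0.0 or n_samples == 0:
        return np.zeros((n_channels, n_samples), dtype=np.float32)
    n_fft = scipy.fft.next_fast_len(n_samples, real=True)  # avoid prime lengths
    n_freq = n_fft // 2 + 1
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs_hz)
    weight = np.zeros(n_freq)
    weight[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal((n_channels, n_freq))
            + 1j * rng.standard_normal((n_channels, n_freq))).astype(np.complex64)
    spec *= weight.astype(np.float32)
    x = scipy.fft.irfft(spec, n=n_fft, axis=1)[:, :n_samples]
    x /= x.std(axis=1, keepdims=True)
    x *= sd
    return x.astype(np.float32)


def pd_template(fs_hz: float, amplitude: float, sharp_sigma_ms: float = 2.0,
                slow_sigma_ms: float = 5.0, slow_delay_ms: float = 8.0,
                slow_frac: float = 0.6) -> np.ndarray:
    """Stereotyped PD waveform: a sharp negative transient followed by a
    slower positive wave (difference of Gaussians, ~30 ms total)."""
    s1 = sharp_sigma_ms / 1000.0
    s2 = slow_sigma_ms / 1000.0
    d = slow_delay_ms / 1000.0
    t = np.arange(-4 * s1, d + 4 * s2, 1.0 / fs_hz)
    w = -np.exp(-0.5 * (t / s1) ** 2) + slow_frac * np.exp(-0.5 * ((t - d) / s2) ** 2)
    return (amplitude * w).astype(np.float32)


def _evoked_template(fs_hz: float, sigma_ms: float = 3.0,
                     latency_ms: float = 3.0) -> np.ndarray:
    s = sigma_ms / 1000.0
    lat = latency_ms / 1000.0
    t = np.arange(0.0, lat + 4 * s, 1.0 / fs_hz)
    return (-np.exp(-0.5 * ((t - lat) / s) ** 2)).astype(np.float32)


def draw_pulse_outcomes(protocol: PulseProtocol, model: GroundTruthModel,
                        rng: np.random.Generator) -> PulseOutcomes:
    """Draw per-trial PD labels and evoked amplitudes without rendering LFP.

    PD probability is the Boltzmann curve at the trial's level, multiplied by
    ``suppress_rho`` when the most recent PD trial began strictly less than
    ``suppress_window_s`` before this trial's onset.  The evoked amplitude is
    ``evoked_gain * level`` scaled by the desensitization state plus Gaussian
    measurement noise.
    """
    n = protocol.n_events
    is_pd = np.zeros(n, dtype=bool)
    amp = np.zeros(n)
    p_real = np.zeros(n)
    desens = np.zeros(n)
    d_state = 0.0
    t_prev = None
    t_last_pd = None
    for i, ev in enumerate(protocol.events):
        if t_prev is not None:
            d_state *= math.exp(-(ev.onset_s - t_prev) / model.desens_tau_s)
        factor = max(0.0, 1.0 - d_state)
        p = float(model.p_pd(ev.level))
        if (t_last_pd is not None
                and (ev.onset_s - t_last_pd) < model.suppress_window_s):
            p *= model.suppress_rho
        pd = rng.random() < p
        is_pd[i] = pd
        p_real[i] = p
        desens[i] = factor
        amp[i] = (model.evoked_gain * ev.level * factor
                  + rng.normal(0.0, model.noise_sd))
        d_state += model.desens_delta * ev.level
        t_prev = ev.onset_s
        if pd:
            t_last_pd = ev.onset_s
    return PulseOutcomes(is_pd, amp, p_real, desens)


def _add_at(trace: np.ndarray, start: int, wave: np.ndarray) -> None:
    stop = min(start + len(wave), trace.shape[-1])
    if start >= stop or stop <= 0:
        return
    a = max(start, 0)
    trace[a:stop] += wave[a - start:stop - start]


def simulate_pulse_session(protocol: PulseProtocol, model: GroundTruthModel,
                           seed: int, *, start_pad_s: float = 1.0,
                           end_pad_s: float = 1.0) -> Session:
    """Render a full multi-channel session for a single-pulse protocol.

    Every trial gets a short-latency evoked deflection at the stimulation
    channel (amplitude scaled by level and the desensitization state); PD
    trials additionally get the stereotyped PD waveform, at the network
    latency, on all downstream channels with site-dependent gain; shaped
    background noise is added everywhere.  Identical seeds yield bit-identical
    sessions.
    """
    fs = model.fs_hz
    names, stim_name, gains = channel_layout(model.n_channels)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    outcomes = draw_pulse_outcomes(protocol, model, rng)

    n_samples = int(round((start_pad_s + protocol.duration_s + end_pad_s) * fs))
    last_needed = start_pad_s + protocol.onsets_s[-1] + 0.5 if protocol.n_events else 0.0
    if last_needed * fs > n_samples:
        raise InvalidArgumentError("protocol longer than the requested recording span")

    lfp = powerlaw_noise(model.n_channels, n_samples, model.noise_exponent,
                         model.noise_sd, fs, rng)
    stim_idx = names.index(stim_name)
    evoked = _evoked_template(fs)
    base_pd = pd_template(fs, 1.0)
    lat = int(round(model.pd_latency_ms / 1000.0 * fs))
    # small multiplicative amplitude jitter keeps PD statistics realistic
    jitter = np.exp(rng.normal(0.0, 0.1, size=protocol.n_events))

    events = []
    for i, ev in enumerate(protocol.events):
        onset = ev.onset_s + start_pad_s
        events.append(replace(ev, onset_s=onset))
        i0 = int(round(onset * fs))
        _add_at(lfp[stim_idx], i0, evoked * np.float32(outcomes.amplitude[i]))
        if outcomes.is_pd[i]:
            wave = base_pd * np.float32(model.pd_amplitude * jitter[i])
            for c in range(model.n_channels):
                if gains[c] > 0.0:
                    _add_at(lfp[c], i0 + lat, wave * np.float32(gains[c]))

    return Session(
        lfp=lfp, fs_hz=fs, events=tuple(events), channel_names=names,
        truth_pd=outcomes.is_pd,
        meta={"seed": int(seed), "stim_channel": stim_name,
              "kind": "pulse", "isi_s": protocol.isi_s,
              "a_true": model.a_true, "b_true": model.b_true},
    )


def _power_to_level(power_mW: float, scale: IntensityScale) -> float:
    """Clipped piecewise-linear inverse of the calibration table."""
    if power_mW <= 0:
        return -np.inf
    levels = np.asarray(scale.levels, dtype=float)
    power = np.asarray(scale.power_mW, dtype=float)
    return float(np.interp(power_mW, power, levels))


def draw_train_outcome(train: TrainProtocol, model: GroundTruthModel,
                       ad_model: ADAccumulationModel, rng: np.random.Generator,
                       scale: Optional[IntensityScale] = None) -> TrainDraw:
    """Draw per-pulse PD labels and the AD outcome for one train.

    The per-pulse PD probability is the Boltzmann curve at the train's
    intensity multiplied by ``desens_pulse_decay ** pulse_index``; the AD is
    drawn from the accumulation logistic at the train's final PD count, and
    its total duration (train start to last spike) is drawn around 23 s.
    """
    scale = scale or IntensityScale.default()
    level = _power_to_level(train.power_mW, scale)
    p0 = 0.0 if not np.isfinite(level) else float(model.p_pd(level))
    k = np.arange(train.n_pulses)
    p = p0 * ad_model.desens_pulse_decay ** k
    pulse_pd = rng.random(train.n_pulses) < p
    n_pd = int(pulse_pd.sum())
    is_ad = rng.random() < ad_model.p_ad(n_pd)
    dur = 0.0
    if is_ad:
        dur = float(np.clip(rng.normal(23.1, 4.84),
                            train.duration_s + 5.5, train.duration_s + 25.0))
    return TrainDraw(train.power_mW, pulse_pd, bool(is_ad), dur)


def simulate_train_session(train: TrainProtocol, model: GroundTruthModel,
                           ad_model: ADAccumulationModel, seed: int, *,
                           scale: Optional[IntensityScale] = None,
                           pre_s: float = 5.0, post_s: float = 36.0) -> Session:
    """Render a train-stimulation session, including the afterdischarge.

    PD waveforms follow PD-labelled pulses at the network latency; when the
    drawn outcome is an AD, a self-sustaining high-amplitude spike envelope
    runs from the end of the train until the drawn AD duration (measured from
    train start) elapses.
    """
    if train.is_empty:
        raise InvalidArgumentError("cannot simulate an empty train")
    fs = model.fs_hz
    names, stim_name, gains = channel_layout(model.n_channels)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draw = draw_train_outcome(train, model, ad_model, rng, scale)

    n_samples = int(round((pre_s + train.end_s + post_s) * fs))
    lfp = powerlaw_noise(model.n_channels, n_samples, model.noise_exponent,
                         model.noise_sd, fs, rng)
    stim_idx = names.index(stim_name)
    evoked = _evoked_template(fs)
    base_pd = pd_template(fs, 1.0)
    lat = int(round(model.pd_latency_ms / 1000.0 * fs))
    level = _power_to_level(train.power_mW, scale or IntensityScale.default())

    events = []
    for k, onset in enumerate(train.pulse_onsets_s):
        t = onset + pre_s
        events.append(StimulusEvent(0, k, int(np.clip(round(level), 1, 99)) if
                                    np.isfinite(level) else 1,
                                    train.power_mW, t, train.pulse_width_ms))
        i0 = int(round(t * fs))
        amp = model.evoked_gain * (level if np.isfinite(level) else 0.0)
        _add_at(lfp[stim_idx], i0, evoked * np.float32(max(amp, 0.0)))
        if draw.pulse_pd[k]:
            wave = base_pd * np.float32(model.pd_amplitude)
            for c in range(model.n_channels):
                if gains[c] > 0.0:
                    _add_at(lfp[c], i0 + lat, wave * np.float32(gains[c]))

    if draw.is_ad:
        spike = pd_template(fs, 1.5 * model.pd_amplitude, sharp_sigma_ms=1.5,
                            slow_sigma_ms=4.0, slow_delay_ms=6.0)
        t_spike = pre_s + train.end_s
        t_stop = pre_s + draw.ad_duration_s
        period = 1.0 / 12.0  # 12 Hz poly-spike envelope
        while t_spike < t_stop:
            i0 = int(round((t_spike + rng.uniform(-0.01, 0.01)) * fs))
            a = np.float32(np.exp(rng.normal(0.0, 0.15)))
            for c in range(model.n_channels):
                if gains[c] > 0.0:
                    _add_at(lfp[c], i0, spike * (a * np.float32(gains[c])))
            t_spike += period

    return Session(
        lfp=lfp, fs_hz=fs, events=tuple(events), channel_names=names,
        truth_pd=draw.pulse_pd, truth_ad=draw.is_ad,
        meta={"seed": int(seed), "stim_channel": stim_name, "kind": "train",
              "ad_duration_true_s": draw.ad_duration_s,
              "train_start_s": pre_s, "train_end_s": pre_s + train.end_s},
    )


def inject_spontaneous_iis(session: Session, rate_hz: float, seed: int) -> Session:
    """Add Poisson-timed spontaneous interictal spikes to a session.

    Injected waveforms are the network PD template on all downstream channels
    at times independent of the stimulus; the injection times are recorded in
    ``session.iis_times`` so detector specificity can be scored.
    """
    if rate_hz < 0:
        raise InvalidArgumentError("rate_hz must be non-negative")
    if rate_hz == 0:
        return session
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    T = session.duration_s
    n = rng.poisson(rate_hz * T)
    times = np.sort(rng.uniform(0.0, T, size=n))
    lfp = session.lfp.copy()
    names = session.channel_names
    stim = session.meta.get("stim_channel")
    try:
        _, _, gains = channel_layout(len(names))
    except InvalidArgumentError:
        gains = np.ones(len(names))
    # amplitude model must match stimulus-evoked PDs: IIS are indistinguishable
    fs = session.fs_hz
    wave = pd_template(fs, 400.0)
    for t in times:
        i0 = int(round(t * fs))
        for c, name in enumerate(names):
            if name != stim and gains[c] > 0.0:
                _add_at(lfp[c], i0, wave * np.float32(gains[c]))
    prev = session.iis_times if session.iis_times is not None else np.empty(0)
    return Session(lfp=lfp, fs_hz=session.fs_hz, events=session.events,
                   channel_names=names, truth_pd=session.truth_pd,
                   truth_ad=session.truth_ad,
                   iis_times=np.sort(np.concatenate([prev, times])),
                   meta=dict(session.meta))


# Packaged pharmacology scenarios.  Generating I50s are the group means of the
# baseline, PTZ, and PTZ+LEV conditions; everything else uses the default
# noise/desensitization/suppression settings.
SCENARIOS: dict[str, dict] = {
    "pharma-baseline": {"a_true": 16.4},
    "pharma-ptz": {"a_true": 14.5},
    "pharma-ptz-lev": {"a_true": 15.7},
}


def scenario_model(name: str, **overrides) -> GroundTruthModel:
    if name not in SCENARIOS:
        raise InvalidArgumentError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}")
    params = dict(SCENARIOS[name])
    params.update(overrides)
    return GroundTruthModel(**params)


def make_scenario_session(name: str, seed: int, *, n_blocks: int = 60,
                          isi_s: float = 3.0,
                          scale: Optional[IntensityScale] = None,
                          **model_overrides):
    """Simulate one packaged-scenario session (default 20 levels x 60 blocks,
    3-s ISI).  Returns ``(session, protocol)``."""
    from .protocol import make_pulse_protocol

    scale = scale or IntensityScale.default()
    model = scenario_model(name, **model_overrides)
    protocol = make_pulse_protocol(scale, n_blocks, isi_s, seed=seed)
    session = simulate_pulse_session(protocol, model, seed)
    session.meta["scenario"] = name
    return session, protocol
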