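"""Session containers and the end-to-end pipeline.

Sessions are stored as HDF5 (/lfp float32 channels x samples, /events column
datasets, /truth booleans, root attrs for sampling rate, seed and generator
metadata); all tabular derivatives are CSV so results stay diffable.  Every
pipeline run embeds the resolved configuration hash and seed in its outputs,
so re-running a hash reproduces the artifacts bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from . import __version__
from .detect import detect_pds, sorted_peak_curve
from .doseresponse import binned_i50, fit_boltzmann, tabulate_ratios
from .errors import InvalidArgumentError, SchemaError
from .protocol import IntensityScale, PulseProtocol, StimulusEvent, make_pulse_protocol
from .synth import Session, make_scenario_session

__all__ = ["read_session", "write_session", "RunConfig", "run_pipeline"]

_EVENT_COLS = ("block", "idx", "level", "power_mW", "onset_s", "pulse_width_ms")


def write_session(session: Session, path) -> None:
    """Write a session to HDF5 (lossless float32 round trip)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("lfp", data=session.lfp.astype(np.float32),
                         chunks=True, compression="gzip", compression_opts=1)
        g = f.create_group("events")
        ev = session.events
        g.create_dataset("block", data=np.array([e.block_index for e in ev], dtype=np.int32))
        g.create_dataset("idx", data=np.array([e.within_block_index for e in ev], dtype=np.int32))
        g.create_dataset("level", data=np.array([e.level for e in ev], dtype=np.int32))
        g.create_dataset("power_mW", data=np.array([e.power_mW for e in ev]))
        g.create_dataset("onset_s", data=np.array([e.onset_s for e in ev]))
        g.create_dataset("pulse_width_ms", data=np.array([e.pulse_width_ms for e in ev]))
        t = f.create_group("truth")
        if session.truth_pd is not None:
            t.create_dataset("pd", data=session.truth_pd.astype(bool))
        if session.truth_ad is not None:
            t.attrs["ad"] = bool(session.truth_ad)
        if session.iis_times is not None:
            f.create_dataset("iis_times", data=session.iis_times)
        f.attrs["fs_hz"] = session.fs_hz
        f.attrs["channel_names"] = json.dumps(list(session.channel_names))
        f.attrs["meta"] = json.dumps(session.meta, default=str)
        f.attrs["opdt_version"] = __version__


def read_session(path) -> Session:
    """Read a session written by :func:`write_session`.

    Raises :class:`SchemaError` naming the missing group/column on any layout
    violation (including truncated files).
    """
    try:
        with h5py.File(path, "r") as f:
            if "lfp" not in f:
                raise SchemaError(f"{path}: missing dataset /lfp")
            if "events" not in f:
                raise SchemaError(f"{path}: missing group /events")
            g = f["events"]
            for col in _EVENT_COLS:
                if col not in g:
                    raise SchemaError(f"{path}: missing column /events/{col}")
            for attr in ("fs_hz", "channel_names"):
                if attr not in f.attrs:
                    raise SchemaError(f"{path}: missing attribute {attr!r}")
            lfp = f["lfp"][()]
            cols = {c: g[c][()] for c in _EVENT_COLS}
            events = tuple(
                StimulusEvent(int(b), int(i), int(l), float(p), float(o), float(w))
                for b, i, l, p, o, w in zip(cols["block"], cols["idx"],
                                            cols["level"], cols["power_mW"],
                                            cols["onset_s"], cols["pulse_width_ms"])
            )
            truth_pd = None
            truth_ad = None
            if "truth" in f:
                if "pd" in f["truth"]:
                    truth_pd = f["truth"]["pd"][()].astype(bool)
                if "ad" in f["truth"].attrs:
                    truth_ad = bool(f["truth"].attrs["ad"])
            iis = f["iis_times"][()] if "iis_times" in f else None
            return Session(
                lfp=lfp, fs_hz=float(f.attrs["fs_hz"]), events=events,
                channel_names=tuple(json.loads(f.attrs["channel_names"])),
                truth_pd=truth_pd, truth_ad=truth_ad, iis_times=iis,
                meta=json.loads(f.attrs.get("meta", "{}")),
            )
    except (OSError, KeyError) as exc:
        raise SchemaError(f"{path}: not a readable session container ({exc})") from exc


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (fully recorded in the
    outputs together with the package version and a config hash)."""

    scenario: Optional[str] = None      # packaged scenario name, or
    input_path: Optional[str] = None    # path to a recorded/simulated session
    protocol_path: Optional[str] = None
    n_blocks: int = 60
    isi_s: float = 3.0
    n_levels: int = 20
    channel: Optional[str] = None       # None -> automatic selection
    pre_s: float = 0.05
    post_s: float = 0.15
    search_window_s: tuple = (0.005, 0.100)
    rms_window_ms: float = 10.0
    threshold: Optional[float] = None   # None -> automatic largest-gap
    n_boot: int = 200
    axis: str = "level"
    bin_blocks: Optional[int] = None
    seed: int = 0
    outdir: str = "opdt-run"
    figures: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise InvalidArgumentError(f"unknown config keys: {sorted(bad)}")
        if "search_window_s" in raw:
            raw["search_window_s"] = tuple(raw["search_window_s"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["search_window_s"] = list(self.search_window_s)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location and
        figure toggles excluded, so relocated re-runs keep the same hash)."""
        d = self.to_dict()
        d.pop("outdir", None)
        d.pop("figures", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    detections: object
    curve: object
    fit: object
    timecourse: object
    paths: dict
    log: list


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Simulate-or-load, detect, tabulate, fit, and write the artifact bundle.

    Deterministic given the seeds in ``config``; the run log records per-stage
    counts (events, exclusions, PD calls, fit status) and is written alongside
    the CSV/JSON artifacts.
    """
    from .protocol import read_protocol

    log: list[str] = []
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.scenario is not None:
        session, protocol = make_scenario_session(
            config.scenario, config.seed, n_blocks=config.n_blocks,
            isi_s=config.isi_s)
        log.append(f"simulated scenario {config.scenario!r} seed={config.seed}")
    elif config.input_path is not None:
        session = read_session(config.input_path)
        if config.protocol_path is not None:
            protocol = read_protocol(config.protocol_path)
        else:
            protocol = _protocol_from_session(session)
        log.append(f"loaded session {config.input_path}")
    else:
        raise InvalidArgumentError("config needs a scenario or an input_path")
    log.append(f"events: {len(session.events)}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        detections = detect_pds(
            session, config.channel, pre_s=config.pre_s, post_s=config.post_s,
            search_window_s=tuple(config.search_window_s),
            rms_window_ms=config.rms_window_ms, threshold=config.threshold)
    log.append(f"channel: {detections.channel}; threshold: "
               f"{detections.threshold:.4g}; excluded: {len(detections.excluded)}; "
               f"PD calls: {int(detections.is_pd.sum())}/{detections.n_trials}")

    curve = tabulate_ratios(detections, protocol)
    fit = fit_boltzmann(curve, n_boot=config.n_boot, seed=config.seed,
                        axis=config.axis)
    log.append(f"fit: I50={fit.a:.4f} b={fit.b:.4f} converged={fit.converged}")

    timecourse = None
    if config.bin_blocks:
        timecourse = binned_i50(detections, protocol, config.bin_blocks,
                                axis=config.axis)
        log.append(f"timecourse: {len(timecourse)} bins of {config.bin_blocks} blocks")

    stamp = {"config": config.to_dict(), "config_hash": config.config_hash,
             "seed": config.seed, "opdt_version": __version__}
    paths = {}
    paths["detections"] = outdir / "detections.csv"
    detections.to_frame().to_csv(paths["detections"], index=False)
    paths["curve"] = outdir / "curve.csv"
    curve.to_frame().to_csv(paths["curve"], index=False)
    paths["fit"] = outdir / "fit.json"
    with open(paths["fit"], "w") as fh:
        json.dump({**stamp, "fit": fit.to_dict()}, fh, indent=1)
    if timecourse is not None:
        paths["timecourse"] = outdir / "timecourse.csv"
        timecourse.to_csv(paths["timecourse"], index=False)
    if config.figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        from .plotting import plot_response_curve, plot_sorted_peaks

        ax = plot_response_curve(curve, fit)
        paths["curve_png"] = outdir / "curve.png"
        ax.figure.savefig(paths["curve_png"], dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
        per_level, _ = sorted_peak_curve(detections.max_rms,
                                         detections.trial_events)
        ax = plot_sorted_peaks(per_level, detections.threshold)
        paths["peaks_png"] = outdir / "sorted_peaks.png"
        ax.figure.savefig(paths["peaks_png"], dpi=150, bbox_inches="tight")
        plt.close(ax.figure)

    paths["log"] = outdir / "run_log.txt"
    with open(paths["log"], "w") as fh:
        fh.write(f"opdt {__version__} config_hash={config.config_hash}\n")
        fh.write("\n".join(log) + "\n")
    return PipelineResult(config, detections, curve, fit, timecourse,
                          {k: str(v) for k, v in paths.items()}, log)


def _protocol_from_session(session: Session) -> PulseProtocol:
    """Reconstruct a pulse protocol from a session's event table (used when a
    recorded session arrives without its protocol sidecar)."""
    ev = session.events
    if not ev:
        raise InvalidArgumentError("session has no events")
    levels = sorted({e.level for e in ev})
    powers = {}
    for e in ev:
        powers.setdefault(e.level, e.power_mW)
    scale = IntensityScale(tuple(levels), tuple(powers[l] for l in levels))
    n_blocks = max(e.block_index for e in ev) + 1
    onsets = [e.onset_s for e in ev]
    isi = float(np.median(np.diff(onsets))) if len(onsets) > 1 else 1.0
    return PulseProtocol(scale, n_blocks, isi, ev[0].pulse_width_ms, -1, tuple(ev))
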