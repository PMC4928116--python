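"""Paradigm-faithful synthetic FAF sessions with known ground truth.

The generator emulates the experimental paradigm (sustained vocalizations
carrying brief pitch-shift perturbations) well enough to exercise every
downstream analysis stage: a voice F0 contour with programmed compensatory
responses and autoregressive baseline jitter, and a multichannel EEG stream
with programmed N1/P2 deflections, block-coupled theta-band sources,
background noise and injected high-amplitude artifact transients.

The generative model is a stand-in: the study it emulates reports no
generative description of its signals, so every waveform shape here (response
template, jitter process, artifact morphology) is a documented package choice,
not a reconstruction.  See ``docs/methods.md``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import EEGGroundTruth, ParadigmConfig, VocalGroundTruth
from .montage import MASTOIDS, default_montage

__all__ = [
    "Schedule",
    "SyntheticSession",
    "draw_schedule",
    "generate_vocal_session",
    "generate_eeg_session",
    "generate_session",
]


@dataclass
class Schedule:
    """Realized timing of one session: vocalization spans and shift events."""

    vocalization_spans_s: list[tuple[float, float]]
    event_onsets_s: np.ndarray  # snapped to the EEG sample grid, ascending
    event_magnitudes_cents: np.ndarray
    event_vocalization: np.ndarray  # index of the carrying vocalization

    @property
    def n_events(self) -> int:
        return len(self.event_onsets_s)

    @property
    def duration_s(self) -> float:
        return self.vocalization_spans_s[-1][1] + 1.0


@dataclass
class SyntheticSession:
    """One synthetic session; either signal part may be absent."""

    config: ParadigmConfig
    schedule: Schedule
    vocal_truth: VocalGroundTruth | None = None
    eeg_truth: EEGGroundTruth | None = None
    f0_time_s: np.ndarray | None = None
    f0_hz: np.ndarray | None = None
    eeg: np.ndarray | None = None  # channels x samples, uV
    channel_names: list[str] = field(default_factory=list)
    #: realized signed response magnitude per trial, cents
    trial_response_cents: np.ndarray | None = None

    @property
    def event_onsets_s(self) -> np.ndarray:
        return self.schedule.event_onsets_s

    @property
    def event_magnitudes_cents(self) -> np.ndarray:
        return self.schedule.event_magnitudes_cents

    @property
    def event_samples_eeg(self) -> np.ndarray:
        return np.round(self.event_onsets_s * self.config.eeg_sample_rate).astype(int)


def draw_schedule(cfg: ParadigmConfig, rng: np.random.Generator) -> Schedule:
    """Draw vocalization spans and a balanced, feasible shift schedule.

    Shift magnitudes are assigned by shuffling a globally balanced multiset
    over the session, so per-vocalization assignment is random while total
    counts per magnitude stay exactly equal.  Within each vocalization the
    first-shift delay and ISIs are redrawn until the last epoch tail fits
    inside the vocalization (feasibility of the minimal schedule is already
    guaranteed by ``ParadigmConfig``).
    """
    n_mag = len(cfg.shift_magnitudes_cents)
    mags = np.repeat(np.asarray(cfg.shift_magnitudes_cents, float), cfg.n_trials // n_mag)
    rng.shuffle(mags)

    spans: list[tuple[float, float]] = []
    onsets: list[float] = []
    voc_idx: list[int] = []
    t = 0.0
    k = cfg.shifts_per_vocalization
    for v in range(cfg.n_vocalizations):
        t += rng.uniform(*cfg.inter_vocalization_gap_s)
        dur = rng.uniform(*cfg.vocalization_duration_s)
        for _ in range(10_000):
            d0 = rng.uniform(*cfg.first_shift_delay_ms) / 1000.0
            isis = rng.uniform(*cfg.isi_range_ms, size=k - 1) / 1000.0
            rel = d0 + np.concatenate([[0.0], np.cumsum(isis)])
            if rel[-1] + cfg.epoch_tail_s <= dur:
                break
        else:  # pragma: no cover - config validation makes this unreachable
            raise RuntimeError("could not draw a feasible shift schedule")
        spans.append((t, t + dur))
        onsets.extend(t + rel)
        voc_idx.extend([v] * k)
        t += dur

    # snap onsets to the EEG sample grid so epochs align exactly
    onsets_arr = np.round(np.asarray(onsets) * cfg.eeg_sample_rate) / cfg.eeg_sample_rate
    return Schedule(
        vocalization_spans_s=spans,
        event_onsets_s=onsets_arr,
        event_magnitudes_cents=mags[: len(onsets_arr)],
        event_vocalization=np.asarray(voc_idx, int),
    )


def _ar1(n: int, sd: float, tau_s: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary first-order autoregressive noise with SD ``sd``."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    phi = math.exp(-1.0 / (fs * tau_s))
    e = rng.normal(0.0, sd * math.sqrt(1.0 - phi * phi), size=n)
    x0 = rng.normal(0.0, sd)
    out, _ = signal.lfilter([1.0], [1.0, -phi], e, zi=[phi * x0])
    return out


def _response_template(mag_cents: float, cfg: ParadigmConfig, truth: VocalGroundTruth,
                       fs: float) -> np.ndarray:
    """Raised-cosine excursion: rise, plateau of one shift duration, fall."""
    n_rise = max(1, round(truth.rise_ms * fs / 1000.0))
    n_plat = max(1, round(cfg.shift_duration_ms * fs / 1000.0))
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, n_rise + 1) / n_rise))
    return mag_cents * np.concatenate([ramp, np.ones(n_plat), ramp[::-1]])


def _render_f0(cfg: ParadigmConfig, truth: VocalGroundTruth, sched: Schedule,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fs = cfg.f0_sample_rate
    n = int(round(sched.duration_s * fs))
    t = np.arange(n) / fs
    cents = np.zeros(n)
    voiced = np.zeros(n, bool)

    sign = -1.0 if truth.response_direction == "opposing" else 1.0
    trial_mags = np.empty(sched.n_events)
    for i in range(sched.n_events):
        trial_mags[i] = truth.response_magnitude_cents + (
            rng.normal(0.0, truth.magnitude_sd_cents) if truth.magnitude_sd_cents else 0.0
        )

    for v, (start, end) in enumerate(sched.vocalization_spans_s):
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        i1 = min(i1, n)
        voiced[i0:i1] = True
        cents[i0:i1] += _ar1(i1 - i0, truth.jitter_sd_cents, truth.jitter_tau_s, fs, rng)

    signed = sign * np.sign(sched.event_magnitudes_cents) * np.abs(trial_mags)
    for i in range(sched.n_events):
        onset = sched.event_onsets_s[i]
        tmpl = _response_template(signed[i], cfg, truth, fs)
        j0 = int(round((onset + truth.response_latency_ms / 1000.0) * fs))
        j1 = min(j0 + len(tmpl), n)
        cents[j0:j1] += tmpl[: j1 - j0]

    f0 = np.where(voiced, truth.baseline_f0_hz * np.power(2.0, cents / 1200.0), 0.0)
    return t, f0, signed


def _theta_source(n: int, fs: float, rng: np.random.Generator,
                  band: tuple[float, float] = (3.0, 8.0)) -> np.ndarray:
    """Unit-variance band-limited noise source."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _render_eeg(cfg: ParadigmConfig, truth: EEGGroundTruth, sched: Schedule,
                rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    fs = cfg.eeg_sample_rate
    n = int(round(sched.duration_s * fs))
    labels = default_montage(cfg.eeg_channels)
    scalp = np.array([lab not in MASTOIDS for lab in labels])

    eeg = (rng.normal(0.0, truth.noise_sd_uv, size=(cfg.eeg_channels, n))
           if truth.noise_sd_uv > 0 else np.zeros((cfg.eeg_channels, n)))

    # theta-band sources: one common source per coupling block, mixed with a
    # per-channel independent source at the block's strength
    if truth.theta_amp_uv > 0:
        in_block = np.zeros(cfg.eeg_channels, bool)
        for chans, strength in truth.theta_blocks:
            common = _theta_source(n, fs, rng)
            for c in chans:
                if not 0 <= c < cfg.eeg_channels:
                    raise ValueError(f"theta block channel {c} out of range")
                own = _theta_source(n, fs, rng)
                eeg[c] += truth.theta_amp_uv * (
                    math.sqrt(strength) * common + math.sqrt(1.0 - strength) * own
                )
                in_block[c] = True
        for c in np.nonzero(scalp & ~in_block)[0]:
            eeg[c] += truth.theta_amp_uv * _theta_source(n, fs, rng)

    # event-related deflections on every scalp channel
    ev_samples = np.round(sched.event_onsets_s * fs).astype(int)
    for i, s0 in enumerate(ev_samples):
        mag = float(sched.event_magnitudes_cents[i])
        tmpl = np.zeros(int(round(0.5 * fs)))  # 0..500 ms post onset
        tt = np.arange(len(tmpl)) * 1000.0 / fs
        for comp, width in ((truth.n1.get(mag), truth.n1_width_ms),
                            (truth.p2.get(mag), truth.p2_width_ms)):
            if comp is None:
                raise ValueError(f"no programmed ERP for magnitude {mag} cents")
            amp, lat = comp
            tmpl += amp * np.exp(-0.5 * ((tt - lat) / width) ** 2)
        j1 = min(s0 + len(tmpl), n)
        eeg[scalp, s0:j1] += tmpl[: j1 - s0]

    # injected artifact transients: biphasic pulse with two sharp Gaussian
    # lobes, spanning [-100, +200] ms around the epoch's shift onset
    dur = truth.artifact_duration_ms / 1000.0
    for epoch_idx, chan, amp in truth.artifacts:
        if not 0 <= epoch_idx < sched.n_events:
            raise ValueError(f"artifact epoch index {epoch_idx} out of range")
        if not 0 <= chan < cfg.eeg_channels:
            raise ValueError(f"artifact channel {chan} out of range")
        p0 = ev_samples[epoch_idx] - int(round(0.1 * fs))
        npulse = int(round(dur * fs))
        if p0 < 0 or p0 + npulse > n:
            raise ValueError("artifact injection outside recording bounds")
        tt = np.arange(npulse) / fs
        lobe_sd = 0.015
        pulse = amp * (np.exp(-0.5 * ((tt - dur / 3) / lobe_sd) ** 2)
                       - np.exp(-0.5 * ((tt - 2 * dur / 3) / lobe_sd) ** 2))
        eeg[chan, p0:p0 + npulse] += pulse

    return eeg, labels


def generate_session(
    cfg: ParadigmConfig,
    vocal_truth: VocalGroundTruth | None = None,
    eeg_truth: EEGGroundTruth | None = None,
    seed: int | np.random.Generator | None = None,
) -> SyntheticSession:
    """Generate a full session (voice and/or EEG) from one seeded stream.

    Randomness is drawn strictly in the order schedule -> voice -> EEG from a
    single generator, so regenerating with the same seed is bit-identical.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sched = draw_schedule(cfg, rng)
    sess = SyntheticSession(config=cfg, schedule=sched,
                            vocal_truth=vocal_truth, eeg_truth=eeg_truth)
    if vocal_truth is not None:
        sess.f0_time_s, sess.f0_hz, sess.trial_response_cents = _render_f0(
            cfg, vocal_truth, sched, rng)
    if eeg_truth is not None:
        sess.eeg, sess.channel_names = _render_eeg(cfg, eeg_truth, sched, rng)
    return sess


def generate_vocal_session(cfg: ParadigmConfig, truth: VocalGroundTruth,
                           seed: int | np.random.Generator | None = None) -> SyntheticSession:
    """Voice-only session: F0 contour plus event schedule."""
    return generate_session(cfg, vocal_truth=truth, seed=seed)


def generate_eeg_session(cfg: ParadigmConfig, truth: EEGGroundTruth,
                         seed: int | np.random.Generator | None = None) -> SyntheticSession:
    """EEG-only session: continuous multichannel EEG plus event schedule."""
    return generate_session(cfg, eeg_truth=truth, seed=seed)
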