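"""Auditory ERP pipeline: filter, epoch, artifact-screen, re-reference,
average, and measure N1/P2 peaks.

The pipeline order is fixed: band-pass (1-20 Hz, zero phase) -> segment
(-200..+500 ms) -> artifact detection (+/-55 uV from an 80-ms centered moving
average) -> bad-channel (>20% of segments) and bad-file (>10 bad channels)
rules -> re-reference to the mastoid average -> average retained trials ->
baseline correction -> peak measurement (N1 = minimum in 80-180 ms, P2 =
maximum in 160-280 ms).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import ArtifactRules
from .montage import MASTOIDS

__all__ = [
    "EpochSet",
    "ERPAverage",
    "PeakMeasure",
    "bandpass",
    "segment",
    "moving_average",
    "detect_artifacts",
    "rereference",
    "average_and_baseline",
    "measure_peak",
    "erp_pipeline",
]

PEAK_WINDOWS_MS: dict[str, tuple[float, float]] = {"N1": (80.0, 180.0), "P2": (160.0, 280.0)}
EEG_WINDOW_MS = (-200.0, 500.0)


def bandpass(data: np.ndarray, fs: float, low_hz: float = 1.0, high_hz: float = 20.0,
             order: int = 4) -> np.ndarray:
    """Zero-phase band-pass (4th-order Butterworth, forward-backward)."""
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) at fs={fs}")
    sos = signal.butter(order, (low_hz, high_hz), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, float), axis=-1)


@dataclass
class EpochSet:
    """Epochs x channels x samples EEG segments with screening state."""

    data: np.ndarray  # (n_epochs, n_channels, n_samples), uV
    times_ms: np.ndarray
    fs: float
    channel_names: list[str]
    magnitudes_cents: np.ndarray  # condition label per epoch
    flags: np.ndarray | None = None  # (n_epochs, n_channels) artifact flags
    epoch_keep: np.ndarray | None = None
    bad_channels: list[str] = field(default_factory=list)
    file_ok: bool = True
    dropped_events: list[int] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError as exc:
            raise KeyError(f"channel {name!r} not present") from exc


def segment(data: np.ndarray, fs: float, event_samples: np.ndarray,
            event_magnitudes: np.ndarray, channel_names: list[str],
            window_ms: tuple[float, float] = EEG_WINDOW_MS) -> EpochSet:
    """Cut continuous channels x samples EEG into epochs around events.

    Events whose window leaves the recording are dropped (recorded in
    ``dropped_events``), not an error.
    """
    data = np.asarray(data, float)
    i_lo = int(round(window_ms[0] * fs / 1000.0))
    i_hi = int(round(window_ms[1] * fs / 1000.0))
    times = np.arange(i_lo, i_hi + 1) * 1000.0 / fs

    epochs, mags, dropped = [], [], []
    for k, c in enumerate(np.asarray(event_samples, int)):
        lo, hi = c + i_lo, c + i_hi + 1
        if lo < 0 or hi > data.shape[1]:
            dropped.append(k)
            continue
        epochs.append(data[:, lo:hi])
        mags.append(event_magnitudes[k])
    arr = (np.stack(epochs) if epochs
           else np.empty((0, data.shape[0], len(times))))
    return EpochSet(data=arr, times_ms=times, fs=fs,
                    channel_names=list(channel_names),
                    magnitudes_cents=np.asarray(mags, float),
                    dropped_events=dropped)


def moving_average(x: np.ndarray, n: int) -> np.ndarray:
    """Centered moving average with edge truncation (shorter edge windows)."""
    if n < 1:
        raise ValueError("window must span at least one sample")
    x = np.asarray(x, float)
    length = x.shape[-1]
    i = np.arange(length)
    lo = np.clip(i - n // 2, 0, length)
    hi = np.clip(i + (n - 1) // 2 + 1, 0, length)
    cs = np.concatenate([np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1)
    return (cs[..., hi] - cs[..., lo]) / (hi - lo)


def detect_artifacts(eps: EpochSet, rules: ArtifactRules | None = None) -> EpochSet:
    """Flag artifact-contaminated channel-epochs and apply channel/file rules.

    Returns the same EpochSet with ``flags``, ``epoch_keep``, ``bad_channels``
    and ``file_ok`` filled in: an epoch is rejected when any channel that is
    not globally bad is flagged in it; a channel is bad when flagged in more
    than the allowed fraction of epochs; the file is rejected when more than
    ``max_bad_channels`` channels are bad.
    """
    rules = rules or ArtifactRules()
    w = max(1, int(round(rules.ma_window_ms * eps.fs / 1000.0)))
    if w >= eps.data.shape[-1]:
        raise ValueError("moving-average window must be shorter than the epoch")
    resid = eps.data - moving_average(eps.data, w)
    flags = np.abs(resid).max(axis=-1) > rules.amplitude_bound_uv  # (n_ep, n_ch)

    n_ep = max(1, eps.n_epochs)
    bad = flags.sum(axis=0) / n_ep > rules.bad_channel_fraction
    eps.flags = flags
    eps.bad_channels = [eps.channel_names[i] for i in np.nonzero(bad)[0]]
    eps.epoch_keep = ~(flags[:, ~bad].any(axis=1))
    eps.file_ok = len(eps.bad_channels) <= rules.max_bad_channels
    return eps


def rereference(eps: EpochSet, mastoids: tuple[str, str] = MASTOIDS) -> EpochSet:
    """Re-reference every channel to the average of the two mastoids."""
    idx = [eps.channel_index(m) for m in mastoids]
    for m in mastoids:
        if m in eps.bad_channels:
            raise ValueError(f"mastoid channel {m} is marked bad; cannot re-reference")
    ref = eps.data[:, idx, :].mean(axis=1, keepdims=True)
    eps.data = eps.data - ref
    return eps


@dataclass
class ERPAverage:
    """Condition average: channels x samples, baseline-corrected."""

    data: np.ndarray
    times_ms: np.ndarray
    fs: float
    channel_names: list[str]
    bad_channels: list[str]
    n_retained: int
    retained_fraction: float
    condition: float | None = None


def average_and_baseline(eps: EpochSet, condition: float | None = None) -> ERPAverage:
    """Average retained epochs (optionally one condition) and subtract the
    per-channel mean of the pre-onset baseline."""
    keep = eps.epoch_keep if eps.epoch_keep is not None else np.ones(eps.n_epochs, bool)
    total = keep.copy()
    if condition is not None:
        sel = eps.magnitudes_cents == condition
        keep = keep & sel
        total = sel
    if not keep.any():
        raise ValueError(f"no retained epochs for condition {condition}")
    avg = eps.data[keep].mean(axis=0)
    base = eps.times_ms < 0
    avg = avg - avg[:, base].mean(axis=1, keepdims=True)
    return ERPAverage(data=avg, times_ms=eps.times_ms, fs=eps.fs,
                      channel_names=eps.channel_names, bad_channels=eps.bad_channels,
                      n_retained=int(keep.sum()),
                      retained_fraction=float(keep.sum() / max(1, total.sum())),
                      condition=condition)


@dataclass
class PeakMeasure:
    component: str
    electrode: str
    amplitude_uv: float
    latency_ms: float
    window_ms: tuple[float, float]

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.amplitude_uv)


def measure_peak(avg: ERPAverage, component: str, electrode: str,
                 windows: dict[str, tuple[float, float]] | None = None) -> PeakMeasure:
    """N1/P2 peak amplitude and latency at one electrode.

    N1 is the minimum in 80-180 ms, P2 the maximum in 160-280 ms; flat
    stretches resolve to the earliest sample.  A bad electrode yields a
    missing-value result rather than an error.
    """
    windows = windows or PEAK_WINDOWS_MS
    if component not in windows:
        raise ValueError(f"unknown component {component!r}")
    lo, hi = windows[component]
    ci = avg.channel_names.index(electrode) if electrode in avg.channel_names else None
    if ci is None:
        raise KeyError(f"electrode {electrode!r} not present")
    if electrode in avg.bad_channels:
        return PeakMeasure(component, electrode, float("nan"), float("nan"), (lo, hi))
    sel = (avg.times_ms >= lo) & (avg.times_ms <= hi)
    seg = avg.data[ci, sel]
    t = avg.times_ms[sel]
    i = int(np.argmin(seg)) if component == "N1" else int(np.argmax(seg))
    return PeakMeasure(component, electrode, float(seg[i]), float(t[i]), (lo, hi))


def erp_pipeline(
    data: np.ndarray,
    fs: float,
    event_samples: np.ndarray,
    event_magnitudes: np.ndarray,
    channel_names: list[str],
    rules: ArtifactRules | None = None,
    band: tuple[float, float] = (1.0, 20.0),
    window_ms: tuple[float, float] = EEG_WINDOW_MS,
    mastoids: tuple[str, str] = MASTOIDS,
) -> tuple[EpochSet, dict[float, ERPAverage]]:
    """Full fixed-order ERP pipeline on a continuous recording.

    Returns the screened EpochSet and per-condition baseline-corrected
    averages.  Raises when the file fails the bad-channel rule.
    """
    filt = bandpass(data, fs, *band)
    eps = segment(filt, fs, event_samples, event_magnitudes, channel_names, window_ms)
    eps = detect_artifacts(eps, rules)
    if not eps.file_ok:
        raise ValueError(
            f"file rejected: {len(eps.bad_channels)} bad channels ({eps.bad_channels})")
    eps = rereference(eps, mastoids)
    conditions = sorted(set(eps.magnitudes_cents.tolist()))
    averages = {c: average_and_baseline(eps, c) for c in conditions}
    return eps, averages
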