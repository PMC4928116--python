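"""Vocal compensation analysis of F0 contours under pitch-shifted feedback.

The pipeline converts an F0 contour in Hz to cents relative to a fixed
reference note (G4, 195.997 Hz), segments it into epochs of -200..+700 ms
around each shift onset, averages the artifact-free trials per condition and
quantifies the compensatory response with the 2-SD rule: a valid response is
a contiguous excursion of the averaged cent waveform beyond the baseline mean
+/- 2 baseline SDs, starting at least 60 ms after shift onset and lasting at
least 50 ms.  Magnitude is the peak deviation from the baseline mean within
the excursion; latency is the interpolated first threshold crossing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "REFERENCE_HZ",
    "VocalEpochSet",
    "VocalResponse",
    "hz_to_cents",
    "epoch_vocal",
    "average_epochs",
    "detect_vocal_response",
    "baseline_variability",
]

#: arbitrary reference note G4: cents = 100 * 12 * log2(F0 / reference)
REFERENCE_HZ = 195.997

VOCAL_WINDOW_MS = (-200.0, 700.0)


def hz_to_cents(f0, reference: float = REFERENCE_HZ) -> np.ndarray:
    """Convert F0 in Hz to cents relative to ``reference``.

    Unvoiced samples (``f0 <= 0`` or NaN) propagate as NaN.  One semitone is
    100 cents; one octave 1200.
    """
    if reference <= 0:
        raise ValueError("reference frequency must be positive")
    f0 = np.asarray(f0, float)
    out = np.full(f0.shape, np.nan)
    voiced = np.isfinite(f0) & (f0 > 0)
    out[voiced] = 1200.0 * np.log2(f0[voiced] / reference)
    return out


@dataclass
class VocalEpochSet:
    """Trials x samples cent epochs around shift onsets."""

    data: np.ndarray  # (n_trials, n_samples), cents; NaN where unvoiced
    times_ms: np.ndarray
    magnitudes_cents: np.ndarray  # condition label per trial
    kept: np.ndarray  # bool per trial
    fs: float
    window_ms: tuple[float, float] = VOCAL_WINDOW_MS

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


def epoch_vocal(
    cents: np.ndarray,
    fs: float,
    event_onsets_s: np.ndarray,
    event_magnitudes_cents: np.ndarray,
    window_ms: tuple[float, float] = VOCAL_WINDOW_MS,
    gross_bound_cents: float = 600.0,
) -> VocalEpochSet:
    """Segment a cent waveform into per-trial epochs and screen them.

    A trial is flagged not-kept when its window extends past the recording,
    contains missing/unvoiced samples, or strays beyond
    ``gross_bound_cents`` anywhere (automated surrogate for the study's
    visual screening of interrupted or mistracked trials).
    """
    cents = np.asarray(cents, float)
    i_lo = int(round(window_ms[0] * fs / 1000.0))
    i_hi = int(round(window_ms[1] * fs / 1000.0))
    n_s = i_hi - i_lo + 1
    times = (np.arange(i_lo, i_hi + 1)) * 1000.0 / fs

    n_tr = len(event_onsets_s)
    data = np.full((n_tr, n_s), np.nan)
    kept = np.zeros(n_tr, bool)
    for k, onset in enumerate(event_onsets_s):
        c = int(round(onset * fs))
        lo, hi = c + i_lo, c + i_hi + 1
        if lo < 0 or hi > len(cents):
            continue  # window extends past the recording: flagged, not error
        seg = cents[lo:hi]
        data[k] = seg
        kept[k] = bool(
            np.all(np.isfinite(seg)) and np.all(np.abs(seg) <= gross_bound_cents)
        )
    return VocalEpochSet(
        data=data,
        times_ms=times,
        magnitudes_cents=np.asarray(event_magnitudes_cents, float),
        kept=kept,
        fs=fs,
        window_ms=window_ms,
    )


def average_epochs(eps: VocalEpochSet, by_condition: bool = True) -> dict[float, np.ndarray]:
    """Pointwise mean of kept trials, per condition (shift magnitude).

    Raises when a condition has no kept trial, naming the condition.
    """
    conditions = (sorted(set(eps.magnitudes_cents.tolist()))
                  if by_condition else [None])
    out: dict[float, np.ndarray] = {}
    for cond in conditions:
        sel = eps.kept if cond is None else eps.kept & (eps.magnitudes_cents == cond)
        if not sel.any():
            raise ValueError(f"no kept trials for condition {cond}")
        key = float("nan") if cond is None else float(cond)
        out[key] = eps.data[sel].mean(axis=0)
    return out


@dataclass
class VocalResponse:
    """Validity and quantification of one averaged vocal response."""

    valid: bool
    magnitude_cents: float  # peak |deviation from baseline mean|, >= 0
    latency_ms: float  # interpolated first 2-SD crossing
    baseline_mean_cents: float
    baseline_sd_cents: float
    direction: int = 0  # sign of the excursion peak (-1 downward, +1 upward)

    @classmethod
    def invalid(cls, mean: float, sd: float) -> "VocalResponse":
        return cls(False, float("nan"), float("nan"), mean, sd)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) half-open index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def detect_vocal_response(
    avg: np.ndarray,
    times_ms: np.ndarray,
    n_sd: float = 2.0,
    min_latency_ms: float = 60.0,
    min_duration_ms: float = 50.0,
    merge_gap_ms: float = 10.0,
    sd_floor_cents: float = 1e-9,
) -> VocalResponse:
    """Apply the 2-SD validity rule to an averaged cent waveform.

    Baseline mean and SD come from the pre-onset window.  Threshold crossings
    separated by less than ``merge_gap_ms`` are merged before the 50-ms
    duration rule.  Excursions must *start* at ``min_latency_ms`` or later.
    When several excursions qualify the earliest onset wins, ties broken
    toward the larger magnitude.  A perfectly constant waveform yields an
    invalid-response result; a constant baseline with post-onset structure is
    handled with a tiny SD floor so the threshold remains defined.
    """
    avg = np.asarray(avg, float)
    times_ms = np.asarray(times_ms, float)
    base = times_ms < 0
    if not base.any() or not (~base).any():
        raise ValueError("waveform must span both baseline and post-onset time")
    bmean = float(avg[base].mean())
    bsd = float(avg[base].std(ddof=1))
    if bsd == 0.0:
        if np.allclose(avg, avg[0]):
            return VocalResponse.invalid(bmean, 0.0)
        thr_sd = sd_floor_cents
    else:
        thr_sd = bsd
    thr = n_sd * thr_sd

    dt = times_ms[1] - times_ms[0]
    dev = avg - bmean
    post = times_ms >= 0
    exceed = (np.abs(dev) > thr) & post

    runs = _runs(exceed)
    # merge runs separated by brief re-crossings
    merged: list[tuple[int, int]] = []
    for a, b in runs:
        if merged and (times_ms[a] - times_ms[merged[-1][1] - 1]) < merge_gap_ms:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    candidates = []
    for a, b in merged:
        start = times_ms[a]
        duration = times_ms[b - 1] - times_ms[a] + dt
        if start >= min_latency_ms and duration >= min_duration_ms:
            # peak deviation anywhere after the response onset, to the
            # epoch end: the excursion marks the onset, not the peak bounds
            peak_i = a + int(np.argmax(np.abs(dev[a:])))
            candidates.append((start, -abs(dev[peak_i]), a, b, peak_i))
    if not candidates:
        return VocalResponse.invalid(bmean, bsd)

    candidates.sort()
    _, _, a, b, peak_i = candidates[0]
    magnitude = float(abs(dev[peak_i]))
    direction = int(np.sign(dev[peak_i]))

    # interpolated crossing of the +/- threshold at the excursion onset
    if a > 0 and abs(dev[a]) > abs(dev[a - 1]):
        d0, d1 = abs(dev[a - 1]), abs(dev[a])
        frac = (thr - d0) / (d1 - d0) if d1 > d0 else 1.0
        latency = float(times_ms[a - 1] + frac * dt)
        latency = max(latency, 0.0)
    else:
        latency = float(times_ms[a])
    return VocalResponse(True, magnitude, latency, bmean, bsd, direction)


def baseline_variability(eps: VocalEpochSet, mode: str = "average") -> float:
    """Baseline F0 variability index, in cents.

    mode="average": SD over the pre-onset samples of the averaged waveform
    (the quantity entering the 2-SD detection threshold).  mode="trials":
    pooled SD over the pre-onset samples of every kept trial, an index of the
    raw per-trial vocalization variability that would otherwise be shrunk by
    averaging.
    """
    base = eps.times_ms < 0
    kept = eps.data[eps.kept]
    if kept.size == 0:
        raise ValueError("no kept trials")
    if mode == "average":
        return float(kept.mean(axis=0)[base].std(ddof=1))
    if mode == "trials":
        return float(kept[:, base].std(ddof=1))
    raise ValueError(f"unknown mode {mode!r}")
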