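"""Parameter objects shared across the pipeline.

Every stage of the frequency-altered-feedback (FAF) analysis is driven by a
small number of dataclasses collected here: the experimental paradigm layout,
the programmed ground truth of the synthetic generator, the EEG artifact
rules, the state-space embedding used by the synchronization likelihood, and
the degree sweep of the graph analysis.  All of them validate their fields on
construction so that configuration errors surface early and name the violated
constraint.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field


def _check_interval(name: str, iv: tuple[float, float], positive: bool = True) -> None:
    lo, hi = iv
    if lo > hi:
        raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
    if positive and lo <= 0:
        raise ValueError(f"{name}: bounds must be positive, got {iv}")


@dataclass
class ParadigmConfig:
    """Timing and layout of one FAF session.

    Defaults reproduce the study paradigm: 40 sustained vocalizations of 5-6 s,
    each carrying 5 pitch shifts of 200 ms, inter-stimulus interval 700-900 ms,
    first shift 500-1000 ms after vocal onset, shift magnitudes +50 and +200
    cents assigned in a globally balanced way (100 trials per magnitude), voice
    F0 contour sampled at 1 kHz and 64-channel EEG at 1 kHz.
    """

    n_vocalizations: int = 40
    shifts_per_vocalization: int = 5
    shift_duration_ms: float = 200.0
    isi_range_ms: tuple[float, float] = (700.0, 900.0)
    first_shift_delay_ms: tuple[float, float] = (500.0, 1000.0)
    shift_magnitudes_cents: tuple[float, ...] = (50.0, 200.0)
    vocalization_duration_s: tuple[float, float] = (5.0, 6.0)
    inter_vocalization_gap_s: tuple[float, float] = (2.0, 3.0)
    f0_sample_rate: float = 1000.0
    eeg_channels: int = 64
    eeg_sample_rate: float = 1000.0
    #: time after the last shift onset that must still lie inside the
    #: vocalization so the full analysis epoch is voiced
    epoch_tail_s: float = 0.7

    def __post_init__(self) -> None:
        if self.n_vocalizations < 1 or self.shifts_per_vocalization < 1:
            raise ValueError("n_vocalizations and shifts_per_vocalization must be >= 1")
        if self.shift_duration_ms <= 0:
            raise ValueError("shift_duration_ms must be positive")
        _check_interval("isi_range_ms", self.isi_range_ms)
        _check_interval("first_shift_delay_ms", self.first_shift_delay_ms)
        _check_interval("vocalization_duration_s", self.vocalization_duration_s)
        _check_interval("inter_vocalization_gap_s", self.inter_vocalization_gap_s)
        if self.f0_sample_rate <= 0 or self.eeg_sample_rate <= 0:
            raise ValueError("sample rates must be positive")
        if self.eeg_channels < 1:
            raise ValueError("eeg_channels must be >= 1")
        if not self.shift_magnitudes_cents:
            raise ValueError("shift_magnitudes_cents must be non-empty")
        if self.n_trials % len(self.shift_magnitudes_cents):
            raise ValueError(
                "balanced assignment impossible: "
                f"{self.n_trials} trials cannot be split evenly over "
                f"{len(self.shift_magnitudes_cents)} magnitudes"
            )
        # minimal schedule must fit inside the shortest admissible vocalization
        k = self.shifts_per_vocalization
        min_last_onset_s = (
            self.first_shift_delay_ms[0] + (k - 1) * self.isi_range_ms[0]
        ) / 1000.0
        if min_last_onset_s + self.epoch_tail_s > self.vocalization_duration_s[0]:
            raise ValueError(
                "shift schedule infeasible: minimal schedule (first delay "
                f"{self.first_shift_delay_ms[0]} ms + {k - 1} ISIs of "
                f"{self.isi_range_ms[0]} ms + {self.epoch_tail_s * 1e3:.0f} ms epoch tail) "
                f"does not fit in the shortest vocalization "
                f"({self.vocalization_duration_s[0]} s)"
            )

    @property
    def n_trials(self) -> int:
        return self.n_vocalizations * self.shifts_per_vocalization


@dataclass
class VocalGroundTruth:
    """Programmed vocal behaviour of a synthetic speaker.

    The compensatory response is a raised-cosine excursion (rise/fall
    ``rise_ms``, plateau of one shift duration) of ``response_magnitude_cents``
    that *opposes* the sign of the feedback shift (or follows it, for the
    minority of following responders).  Baseline F0 wobbles as a first-order
    autoregressive process in the cents domain with stationary SD
    ``jitter_sd_cents`` and correlation time ``jitter_tau_s``.
    """

    response_magnitude_cents: float = 12.0
    response_latency_ms: float = 120.0
    response_direction: str = "opposing"  # or "following"
    baseline_f0_hz: float = 200.0
    jitter_sd_cents: float = 5.0
    jitter_tau_s: float = 0.01
    rise_ms: float = 80.0
    magnitude_sd_cents: float = 0.0  # per-trial variability of the magnitude

    def __post_init__(self) -> None:
        if self.response_latency_ms < 0:
            raise ValueError("response_latency_ms must be >= 0")
        if self.jitter_sd_cents < 0:
            raise ValueError("jitter_sd_cents must be >= 0")
        if self.response_direction not in ("opposing", "following"):
            raise ValueError("response_direction must be 'opposing' or 'following'")
        if self.baseline_f0_hz <= 0:
            raise ValueError("baseline_f0_hz must be positive")
        if self.jitter_tau_s <= 0 or self.rise_ms <= 0:
            raise ValueError("jitter_tau_s and rise_ms must be positive")
        if self.magnitude_sd_cents < 0:
            raise ValueError("magnitude_sd_cents must be >= 0")


def _default_n1() -> dict[float, tuple[float, float]]:
    # amplitude (uV, negative), latency (ms); +50-cent shifts elicit longer
    # N1 latencies than +200-cent shifts (145 vs 129 ms)
    return {50.0: (-4.0, 145.0), 200.0: (-4.5, 129.0)}


def _default_p2() -> dict[float, tuple[float, float]]:
    # +50-cent shifts elicit smaller and later P2 than +200 (256 vs 234 ms)
    return {50.0: (4.5, 256.0), 200.0: (6.0, 234.0)}


@dataclass
class EEGGroundTruth:
    """Programmed cortical content of a synthetic EEG session.

    ``n1`` and ``p2`` map shift magnitude (cents) to (amplitude uV, latency
    ms) of the Gaussian-windowed deflection added to every scalp channel at
    each shift onset.  ``theta_blocks`` lists (channel-index set, coupling
    strength in [0, 1]) pairs; channels within a block share a common 3-8 Hz
    source mixed at that strength with a per-channel independent theta source.
    ``artifacts`` lists (epoch index, channel index, amplitude uV) transients.
    """

    n1: dict[float, tuple[float, float]] = field(default_factory=_default_n1)
    p2: dict[float, tuple[float, float]] = field(default_factory=_default_p2)
    n1_width_ms: float = 15.0
    p2_width_ms: float = 20.0
    theta_blocks: tuple[tuple[tuple[int, ...], float], ...] = ()
    theta_amp_uv: float = 10.0
    artifacts: tuple[tuple[int, int, float], ...] = ()
    artifact_duration_ms: float = 300.0
    noise_sd_uv: float = 5.0

    def __post_init__(self) -> None:
        for mag, (amp, lat) in self.n1.items():
            if amp >= 0:
                raise ValueError(f"N1 amplitude must be negative, got {amp} for {mag} cents")
            if lat <= 0:
                raise ValueError("N1 latency must be positive")
        for mag, (amp, lat) in self.p2.items():
            if amp <= 0:
                raise ValueError(f"P2 amplitude must be positive, got {amp} for {mag} cents")
            if lat <= 0:
                raise ValueError("P2 latency must be positive")
        seen: set[int] = set()
        for chans, strength in self.theta_blocks:
            if not 0.0 <= strength <= 1.0:
                raise ValueError(f"coupling strength {strength} outside [0, 1]")
            if seen & set(chans):
                raise ValueError("theta coupling blocks must be disjoint channel sets")
            seen |= set(chans)
        if self.noise_sd_uv < 0:
            raise ValueError("noise_sd_uv must be >= 0")
        if self.theta_amp_uv < 0:
            raise ValueError("theta_amp_uv must be >= 0")


@dataclass
class ArtifactRules:
    """EEG artifact rejection thresholds.

    A channel-in-epoch is flagged when any sample deviates from the channel's
    centered ``ma_window_ms`` moving average by more than ``amplitude_bound_uv``;
    a channel is bad when flagged in more than ``bad_channel_fraction`` of
    epochs; the file is rejected when more than ``max_bad_channels`` channels
    are bad.
    """

    amplitude_bound_uv: float = 55.0
    ma_window_ms: float = 80.0
    bad_channel_fraction: float = 0.20
    max_bad_channels: int = 10

    def __post_init__(self) -> None:
        if min(self.amplitude_bound_uv, self.ma_window_ms, self.bad_channel_fraction) <= 0:
            raise ValueError("artifact rule parameters must be positive")
        if self.max_bad_channels <= 0:
            raise ValueError("max_bad_channels must be positive")


@dataclass
class EmbeddingParams:
    """Time-delay embedding parameters for the synchronization likelihood.

    ``lag`` and ``dim`` define state-space vectors
    ``(x_i, x_{i+lag}, ..., x_{i+(dim-1)lag})``; candidate recurrence partners
    of reference time ``i`` are the ``j`` with ``w1 < |i - j| < w2`` (Theiler
    exclusion ``w1``, search horizon ``w2``); ``p_ref`` is the reference
    recurrence probability that fixes each per-reference cutoff distance.
    """

    lag: int
    dim: int
    w1: int
    w2: int
    p_ref: float = 0.01

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if not 0 < self.w1 < self.w2:
            raise ValueError("need 0 < w1 < w2")
        if not 0.0 < self.p_ref < 1.0:
            raise ValueError("p_ref must lie in (0, 1)")

    @property
    def span(self) -> int:
        """Temporal extent of one embedding vector, in samples."""
        return (self.dim - 1) * self.lag

    @property
    def min_candidates(self) -> int:
        return math.ceil(1.0 / self.p_ref)

    @classmethod
    def for_band(
        cls,
        low_hz: float,
        high_hz: float,
        fs: float,
        n_samples: int | None = None,
        p_ref: float = 0.01,
    ) -> "EmbeddingParams":
        """Standard embedding recipe for a band-limited signal.

        lag = fs / (3*high) rounded, dim = 1 + ceil(3*high/low), Theiler window
        w1 = 2*lag*(dim-1) and w2 capped at the number of state vectors.  When
        ``n_samples`` is given and the recipe leaves no reference time with at
        least ``ceil(1/p_ref)`` candidates (short epochs), the dimension is
        reduced - and w1 relaxed to one embedding span - until feasible.
        """
        if not 0 < low_hz < high_hz < fs / 2:
            raise ValueError("need 0 < low < high < Nyquist")
        lag = max(1, round(fs / (3.0 * high_hz)))
        dim0 = 1 + math.ceil(3.0 * high_hz / low_hz)
        n_min = math.ceil(1.0 / p_ref)

        def build(dim: int, w1_factor: int) -> "EmbeddingParams | None":
            span = (dim - 1) * lag
            if n_samples is not None:
                nv = n_samples - span
            else:
                nv = None
            w1 = max(1, w1_factor * span) if dim > 1 else max(1, w1_factor * lag)
            if nv is None:
                # no length constraint: w2 nominally unbounded, use recipe cap
                w2 = w1 + math.ceil(10.0 / p_ref)
                return cls(lag=lag, dim=dim, w1=w1, w2=w2, p_ref=p_ref)
            if nv <= w1 + 1:
                return None
            w2 = min(nv, w1 + math.ceil(nv / p_ref / 10.0))
            # most generous reference point sits at the series edge
            best = max(0, min(w2 - 1, nv - 1) - w1)
            if best < n_min:
                return None
            return cls(lag=lag, dim=dim, w1=w1, w2=w2, p_ref=p_ref)

        for dim in range(dim0, 1, -1):
            for w1_factor in (2, 1):
                params = build(dim, w1_factor)
                if params is not None:
                    return params
        raise ValueError(
            f"no feasible embedding for {n_samples} samples at p_ref={p_ref}; "
            "use longer epochs or a larger p_ref"
        )


@dataclass
class DegreeSweep:
    """Mean-degree grid used to index binary graphs (default 9..14, step 0.25)."""

    k_min: float = 9.0
    k_max: float = 14.0
    k_step: float = 0.25

    def __post_init__(self) -> None:
        if self.k_min <= 1:
            raise ValueError("k_min must exceed 1")
        if self.k_max < self.k_min or self.k_step <= 0:
            raise ValueError("invalid degree sweep bounds")

    @property
    def values(self) -> list[float]:
        n = int(round((self.k_max - self.k_min) / self.k_step)) + 1
        return [self.k_min + i * self.k_step for i in range(n)]
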