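"""Synchronization likelihood (SL) in the theta band.

SL is a state-space recurrence measure of linear and nonlinear
interdependence between two time series.  Both series are delay-embedded;
for each reference time ``i`` a per-signal cutoff distance is chosen as the
smallest radius within which a fixed fraction ``p_ref`` of candidate times
``j`` (``w1 < |i - j| < w2``) recur.  The likelihood that the partner signal
recurs *simultaneously*, averaged over reference times and symmetrized over
the pair, is the SL: it equals ``p_ref`` for independent signals and 1 for
identical ones.

``sl_matrix`` evaluates all channel pairs of an epoch set at once by
precomputing per-channel recurrence masks, so the pairwise step reduces to
one matrix product per epoch.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .config import EmbeddingParams
from .erp import EpochSet, bandpass

__all__ = [
    "SLMatrix",
    "theta_filter",
    "decimate_epochs",
    "embed",
    "candidate_indices",
    "critical_distance",
    "synchronization_likelihood",
    "sl_matrix",
]

THETA_BAND_HZ = (3.0, 8.0)


def theta_filter(data: np.ndarray, fs: float,
                 band: tuple[float, float] = THETA_BAND_HZ) -> np.ndarray:
    """Zero-phase theta-band (3-8 Hz) filter; same contract as ``bandpass``."""
    return bandpass(data, fs, band[0], band[1])


def decimate_epochs(eps: EpochSet, target_fs: float = 250.0) -> EpochSet:
    """Anti-aliased decimation of an epoch set to ``target_fs`` (FIR)."""
    q = int(round(eps.fs / target_fs))
    if q <= 1:
        return eps
    data = _signal.decimate(eps.data, q, ftype="fir", axis=-1, zero_phase=True)
    return EpochSet(data=data, times_ms=eps.times_ms[::q], fs=eps.fs / q,
                    channel_names=eps.channel_names,
                    magnitudes_cents=eps.magnitudes_cents,
                    flags=eps.flags, epoch_keep=eps.epoch_keep,
                    bad_channels=eps.bad_channels, file_ok=eps.file_ok,
                    dropped_events=eps.dropped_events)


def embed(x: np.ndarray, p: EmbeddingParams) -> np.ndarray:
    """State-space vectors ``(x_i, x_{i+L}, ..., x_{i+(m-1)L})``.

    Returns an (n - (m-1)*L, m) array; errors when the series is too short.
    """
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise ValueError("embed expects a 1-d series")
    if len(x) <= p.span:
        raise ValueError(
            f"series of length {len(x)} too short for span {p.span} embedding")
    if p.dim == 1:
        return x[:, None].copy()
    return np.lib.stride_tricks.sliding_window_view(x, p.span + 1)[:, :: p.lag].copy()


def candidate_indices(n_vectors: int, i: int, p: EmbeddingParams) -> np.ndarray:
    """Indices j with w1 < |i - j| < w2 inside [0, n_vectors)."""
    j = np.arange(n_vectors)
    d = np.abs(j - i)
    return j[(d > p.w1) & (d < p.w2)]


def critical_distance(vectors: np.ndarray, i: int, p: EmbeddingParams) -> float:
    """Smallest cutoff at which the candidate recurrence fraction reaches p_ref.

    With all-distinct distances this is the ceil(p_ref * n_candidates)-th
    smallest Euclidean distance from vector ``i`` to its candidates.
    """
    cand = candidate_indices(len(vectors), i, p)
    if len(cand) < p.min_candidates:
        raise ValueError(
            f"only {len(cand)} candidates at reference {i}, need >= "
            f"{p.min_candidates}; use longer epochs or a larger w2")
    d = np.linalg.norm(vectors[cand] - vectors[i], axis=1)
    k = math.ceil(p.p_ref * len(cand))
    return float(np.partition(d, k - 1)[k - 1])


def _reference_points(nv: int, p: EmbeddingParams, max_refs: int | None) -> np.ndarray:
    # candidates on each side of i: those farther than w1 but nearer than w2
    left = np.clip(np.minimum(np.arange(nv), p.w2 - 1) - p.w1, 0, None)
    right = np.clip(np.minimum(nv - 1 - np.arange(nv), p.w2 - 1) - p.w1, 0, None)
    counts = left + right
    refs = np.nonzero(counts >= p.min_candidates)[0]
    if len(refs) == 0:
        raise ValueError(
            "no reference time has enough recurrence candidates; "
            "use longer epochs or a larger w2")
    if max_refs is not None and len(refs) > max_refs:
        refs = refs[np.linspace(0, len(refs) - 1, max_refs).round().astype(int)]
    return refs


def _recurrence_masks(emb: np.ndarray, refs: np.ndarray,
                      p: EmbeddingParams) -> np.ndarray:
    """Boolean (n_refs, n_vectors) recurrence mask for one embedded signal."""
    nv = len(emb)
    j = np.arange(nv)
    d_ij = np.abs(j[None, :] - refs[:, None])
    cand = (d_ij > p.w1) & (d_ij < p.w2)
    dist = np.linalg.norm(emb[refs][:, None, :] - emb[None, :, :], axis=2)
    dist[~cand] = np.inf
    n_cand = cand.sum(axis=1)
    k = np.ceil(p.p_ref * n_cand).astype(int)
    srt = np.sort(dist, axis=1)
    r = srt[np.arange(len(refs)), k - 1]
    return dist <= r[:, None]


def synchronization_likelihood(x: np.ndarray, y: np.ndarray, p: EmbeddingParams,
                               max_refs: int | None = None) -> float:
    """Symmetrized SL between two equal-length series.

    For each reference time the conditional recurrence fraction of one signal
    given the other is accumulated in both directions and the two averages are
    averaged; values lie in [0, 1] (~p_ref for independent series, 1 for
    identical ones).  Degenerate constant series are rejected.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("SL undefined for a constant series")
    ex, ey = embed(x, p), embed(y, p)
    refs = _reference_points(len(ex), p, max_refs)
    rx = _recurrence_masks(ex, refs, p)
    ry = _recurrence_masks(ey, refs, p)
    hx = rx.sum(axis=1)
    hy = ry.sum(axis=1)
    hxy = (rx & ry).sum(axis=1)
    return float(0.5 * (np.mean(hxy / hx) + np.mean(hxy / hy)))


@dataclass
class SLMatrix:
    """Symmetric channel x channel SL matrix (unit diagonal, NaN where bad)."""

    values: np.ndarray
    channel_names: list[str]
    band_hz: tuple[float, float]
    params: EmbeddingParams
    n_epochs: int = 0


def sl_matrix(
    eps: EpochSet,
    params: EmbeddingParams | None = None,
    band_hz: tuple[float, float] = THETA_BAND_HZ,
    max_refs: int | None = 64,
    use_keep_flags: bool = True,
    exclude: tuple[str, ...] = (),
) -> SLMatrix:
    """Per-epoch pairwise SL of all good channels, averaged over epochs.

    The epoch data are assumed already band-limited (see ``theta_filter`` /
    ``decimate_epochs``).  Bad channels and ``exclude``-listed channels keep
    NaN rows/columns.  Embedding defaults to the band recipe adapted to the
    epoch length.
    """
    n_s = eps.data.shape[-1]
    if params is None:
        params = EmbeddingParams.for_band(band_hz[0], band_hz[1], eps.fs, n_samples=n_s)
    keep = (eps.epoch_keep if (use_keep_flags and eps.epoch_keep is not None)
            else np.ones(eps.n_epochs, bool))
    skip = set(eps.bad_channels) | set(exclude)
    good = [i for i, name in enumerate(eps.channel_names) if name not in skip]
    n_ch = len(eps.channel_names)
    if len(good) < 2:
        raise ValueError("need at least two good channels")

    nv = n_s - params.span
    refs = _reference_points(nv, params, max_refs)
    acc = np.zeros((len(good), len(good)))
    n_used = 0
    for e in np.nonzero(keep)[0]:
        masks = []
        for c in good:
            x = eps.data[e, c]
            if x.std() == 0:
                raise ValueError(
                    f"constant epoch {e} on channel {eps.channel_names[c]}")
            masks.append(_recurrence_masks(embed(x, params), refs, params))
        r = np.stack(masks)  # (n_good, n_refs, nv)
        h = r.sum(axis=2).astype(float)  # per-channel recurrences per ref
        w = r / h[:, :, None]
        flat_r = r.reshape(len(good), -1).astype(float)
        flat_w = w.reshape(len(good), -1)
        s = flat_w @ flat_r.T / len(refs)  # s[a, b] = mean_i h_ab / h_a
        acc += 0.5 * (s + s.T)
        n_used += 1
    if n_used == 0:
        raise ValueError("no retained epochs for SL computation")

    vals = np.full((n_ch, n_ch), np.nan)
    sub = acc / n_used
    np.fill_diagonal(sub, 1.0)
    vals[np.ix_(good, good)] = sub
    return SLMatrix(values=vals, channel_names=list(eps.channel_names),
                    band_hz=band_hz, params=params, n_epochs=n_used)
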