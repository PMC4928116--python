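"""Channel labels for synthetic EEG sessions.

A 64-name 10-10 montage in which the fronto-central electrodes used for
peak statistics (FC1..C4) and the mastoid reference pair (M1/M2) come first,
so that reduced-channel configurations still contain them.
"""
from __future__ import annotations

DEFAULT_64: tuple[str, ...] = (
    "Cz", "FCz", "FC1", "FC2", "FC3", "FC4", "C1", "C2", "C3", "C4",
    "M1", "M2",
    "Fp1", "Fpz", "Fp2", "AF3", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC6", "FT8",
    "T7", "C5", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "AF7", "AF8", "FT9", "FT10",
)

MASTOIDS: tuple[str, str] = ("M1", "M2")

#: fronto-central electrodes entering the peak statistics
STATS_ELECTRODES: tuple[str, ...] = (
    "FC1", "FC2", "FCz", "FC3", "FC4", "C1", "C2", "Cz", "C3", "C4",
)


def default_montage(n_channels: int) -> list[str]:
    """``n_channels`` montage labels, always ending in the mastoid pair."""
    if n_channels < 3:
        raise ValueError("n_channels must be >= 3 (two mastoids + scalp)")
    scalp = [lab for lab in DEFAULT_64 if lab not in MASTOIDS]
    labels = scalp[: n_channels - 2]
    while len(labels) < n_channels - 2:
        labels.append(f"CH{len(labels) + 1:03d}")
    return labels + list(MASTOIDS)
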