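"""Plain-text readers/writers for pipeline inputs and outputs.

Voice contours and event lists are two-column TSV; EEG travels as a
channel x sample TSV matrix with the sampling rate on a comment line
(EDF input is accepted when `mne` is importable); ground truth and summaries
are JSON.
"""
from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import EEGGroundTruth, ParadigmConfig, VocalGroundTruth

__all__ = [
    "write_f0_tsv", "read_f0_tsv",
    "write_events_tsv", "read_events_tsv",
    "write_eeg_tsv", "read_eeg", "read_eeg_tsv",
    "write_json", "load_run_config",
]


def write_f0_tsv(path, time_s, f0_hz) -> None:
    pd.DataFrame({"time_s": time_s, "f0_hz": f0_hz}).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_f0_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["time_s"].to_numpy(float), df["f0_hz"].to_numpy(float)


def write_events_tsv(path, onsets_s, magnitudes_cents) -> None:
    pd.DataFrame({"onset_s": onsets_s, "magnitude_cents": magnitudes_cents}).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_events_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["onset_s"].to_numpy(float), df["magnitude_cents"].to_numpy(float)


def write_eeg_tsv(path, eeg: np.ndarray, channel_names, fs: float) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={fs:g}\n")
        df = pd.DataFrame(eeg, index=list(channel_names))
        df.index.name = "channel"
        df.to_csv(fh, sep="\t", float_format="%.4f")


def read_eeg_tsv(path) -> tuple[np.ndarray, list[str], float]:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# sample_rate_hz="):
            raise ValueError("missing sample-rate header in EEG TSV")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh, sep="\t", index_col="channel")
    return df.to_numpy(float), [str(c) for c in df.index], fs


def read_eeg(path) -> tuple[np.ndarray, list[str], float]:
    """Read EEG from TSV, or from EDF when `mne` is available."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("EDF input requires the optional mne package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return raw.get_data() * 1e6, list(raw.ch_names), float(raw.info["sfreq"])
    return read_eeg_tsv(path)


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2)
        fh.write("\n")


def load_run_config(path) -> dict:
    """Read a YAML run configuration into paradigm/truth objects.

    Recognized top-level sections: ``paradigm``, ``vocal_truth``,
    ``eeg_truth``; each maps directly onto the corresponding dataclass
    fields.  Missing sections fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {
        "paradigm": ParadigmConfig(**raw.get("paradigm", {})),
        "vocal_truth": VocalGroundTruth(**raw.get("vocal_truth", {})),
    }
    eeg_raw = dict(raw.get("eeg_truth", {}))
    for key in ("n1", "p2"):
        if key in eeg_raw:
            eeg_raw[key] = {float(m): tuple(v) for m, v in eeg_raw[key].items()}
    if "theta_blocks" in eeg_raw:
        eeg_raw["theta_blocks"] = tuple(
            (tuple(ch), float(s)) for ch, s in eeg_raw["theta_blocks"])
    if "artifacts" in eeg_raw:
        eeg_raw["artifacts"] = tuple(tuple(a) for a in eeg_raw["artifacts"])
    out["eeg_truth"] = EEGGroundTruth(**eeg_raw)
    return out
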