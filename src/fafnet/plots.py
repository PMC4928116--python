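"""Quick-look figures for averaged responses and network sweeps."""
from __future__ import annotations

import numpy as np
import pandas as pd


def plot_erp_average(avg, electrode: str, ax=None):
    """Averaged ERP waveform at one electrode with N1/P2 windows shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ci = avg.channel_names.index(electrode)
    ax.plot(avg.times_ms, avg.data[ci], lw=1.2, color="k")
    ax.axvspan(80, 180, alpha=0.12, color="tab:blue", label="N1 window")
    ax.axvspan(160, 280, alpha=0.12, color="tab:red", label="P2 window")
    ax.axvline(0, color="grey", lw=0.8)
    ax.set(xlabel="time (ms)", ylabel="amplitude (uV)", title=electrode)
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_degree_sweep(table: pd.DataFrame, group_col: str | None = None, ax=None):
    """C and L as a function of degree K (per group when ``group_col`` given)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 3.5))
    frames = ([(None, table)] if group_col is None
              else list(table.groupby(group_col)))
    for label, df in frames:
        agg = df.groupby("K")[["C", "L"]].mean()
        ax[0].plot(agg.index, agg["C"], marker="o", ms=3, label=str(label))
        ax[1].plot(agg.index, agg["L"], marker="o", ms=3, label=str(label))
    if "C_rand_theory" in table:
        agg = table.groupby("K")[["C_rand_theory", "L_rand_theory"]].mean()
        ax[0].plot(agg.index, agg["C_rand_theory"], ls="--", color="grey",
                   label="random (theory)")
        ax[1].plot(agg.index, agg["L_rand_theory"], ls="--", color="grey",
                   label="random (theory)")
    ax[0].set(xlabel="degree K", ylabel="clustering C")
    ax[1].set(xlabel="degree K", ylabel="harmonic path length L")
    for a in ax:
        a.legend(frameon=False, fontsize=8)
    return ax
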