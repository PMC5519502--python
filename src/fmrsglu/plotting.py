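"""Figures: glutamate/BOLD time course with shaded stimulation blocks."""

from __future__ import annotations

from pathlib import Path

from .params import STIMULATION


def plot_group_timecourse(result, path: str | Path) -> None:
    """Group-mean dGlu (%) and z-normalised BOLD against time, stimulation
    blocks shaded."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tc = result.glu_pct_mean
    fig, ax1 = plt.subplots(figsize=(7, 3.2))
    in_stim = tc.condition_per_bin == STIMULATION
    half = (tc.bin_times[1] - tc.bin_times[0]) / 2 if len(tc.bin_times) > 1 else 8
    for t, s in zip(tc.bin_times, in_stim):
        if s:
            ax1.axvspan(t - half, t + half, color="0.88", lw=0, zorder=0)
    ax1.plot(tc.bin_times, tc.values, "o-", color="crimson", ms=3,
             label=r"$\Delta$Glu (%)")
    ax1.set_xlabel("time (s)")
    ax1.set_ylabel(r"$\Delta$Glu (% of baseline)", color="crimson")
    ax2 = ax1.twinx()
    ax2.plot(result.bold_z_mean.bin_times, result.bold_z_mean.values, "s-",
             color="steelblue", ms=3, label="BOLD (z)")
    ax2.set_ylabel("BOLD (z)", color="steelblue")
    c = result.correlation
    ax1.set_title(f"glutamate vs BOLD: r = {c.r:.3f}, p = {c.p:.3f}")
    fig.tight_layout()
    fig.savefig(str(path))
    plt.close(fig)
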