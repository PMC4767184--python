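"""Minimal TIC plotting."""

from __future__ import annotations

from .tic import TIC
from .semiquant import peak_params


def plot_tic(tic: TIC, ax=None, show_peak: bool = True):
    """Plot one time-signal intensity curve (baseline dashed, peak marked)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(tic.times, tic.s, "o-", ms=3, lw=1, label=tic.subject_id or None)
    ax.axhline(tic.s0, ls="--", lw=0.8, color="grey", label="baseline")
    if show_peak:
        s_max, t_peak, _, _ = peak_params(tic)
        ax.plot([t_peak], [s_max], "r^", ms=6)
    ax.set_xlabel("time since injection (s)")
    ax.set_ylabel("signal (a.u.)")
    if tic.subject_id:
        ax.legend(frameon=False, fontsize=8)
    return ax
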