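"""Plots: stop-codon metagene line plot and decay time-course fits."""

from __future__ import annotations

import numpy as np

from .decay import DecayFit, DecayTimeCourse
from .metagene import MetageneMatrix

__all__ = ["plot_metagene", "plot_decay"]


def plot_metagene(matrices, labels=None, ax=None, highlight=(-17, -16)):
    """Line plot of one or several metagene matrices around the anchor.

    The ribosome-boundary positions (default -17/-16) are shaded; the
    vertical line marks the first nucleotide of the stop codon.
    """
    import matplotlib.pyplot as plt

    if isinstance(matrices, MetageneMatrix):
        matrices = [matrices]
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for i, m in enumerate(matrices):
        label = labels[i] if labels else None
        ax.plot(m.rel_positions, m.values, lw=1.2, label=label)
    ax.axvline(0, color="0.4", ls="--", lw=0.8)
    if highlight:
        ax.axvspan(min(highlight) - 0.5, max(highlight) + 0.5, color="tab:red", alpha=0.15)
    ax.set_xlabel("position relative to stop codon (nt)")
    ax.set_ylabel("5'P read ends")
    if labels:
        ax.legend(frameon=False)
    return ax


def plot_decay(tc: DecayTimeCourse, fit: DecayFit | None = None, ax=None):
    """Per-replicate abundance over the chase on a log scale, with the fits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for r, v in sorted(tc.abundance.items()):
        ax.semilogy(tc.times, v, "o", ms=4, label=f"rep {r}")
    if fit is not None:
        tgrid = np.linspace(tc.times[0], tc.times[-1], 100)
        for f in fit.replicate_fits:
            if f.non_decaying:
                continue
            n0 = tc.abundance[f.replicate][0]
            ax.semilogy(tgrid, n0 * np.exp(-f.decay_rate * tgrid), "-", lw=0.8, alpha=0.7)
        if np.isfinite(fit.half_life_mean):
            ax.set_title(
                f"{tc.transcript_id} [{tc.condition}]  "
                f"t$_{{1/2}}$ = {fit.half_life_mean:.1f} ± {fit.half_life_sd:.1f} min"
            )
    ax.set_xlabel("time after transcription arrest (min)")
    ax.set_ylabel("normalized abundance")
    ax.legend(frameon=False, fontsize=8)
    return ax
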