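"""Optional figures: regression scatter and Bland-Altman agreement plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .agreement import bland_altman
from .plr import AlignedTracePair

__all__ = ["regression_plot", "bland_altman_plot"]


def regression_plot(pairs: list[AlignedTracePair], path: str | Path) -> Path:
    """Scatter of device vs reference percent change, with the identity line."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for pair in pairs:
        a, b = pair.valid_pairs()
        ax.scatter(b, a, s=6, alpha=0.4)
    lims = ax.get_xlim() + ax.get_ylim()
    lo, hi = min(lims), max(lims)
    ax.plot([lo, hi], [lo, hi], "k--", lw=1)
    ax.set_xlabel("reference pupil change (% from mean)")
    ax.set_ylabel("device pupil change (% from mean)")
    ax.set_title("Device vs reference percent change")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def bland_altman_plot(pairs: list[AlignedTracePair], path: str | Path) -> Path:
    """Pooled Bland-Altman plot: differences vs means with bias and limits."""
    a = np.concatenate([p.valid_pairs()[0] for p in pairs])
    b = np.concatenate([p.valid_pairs()[1] for p in pairs])
    ba = bland_altman(a, b)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.means, ba.diffs, s=6, alpha=0.4)
    for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of paired percent changes")
    ax.set_ylabel("difference (device - reference)")
    ax.set_title("Bland-Altman agreement")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
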