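"""Profile plots: z-q with g-q overlay, D_max bars, LGD bars."""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .profiles import DarProfileSet

__all__ = ["plot_dar_pdo", "plot_mad", "plot_lgd"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(5, 4))
    return ax


def plot_dar_pdo(profiles: DarProfileSet, ax=None):
    """DAR (z-q) and PDO (g-q) profiles on twin axes."""
    ax = _get_ax(ax)
    q = profiles.q_grid
    z = [r.pl.mean_z for r in profiles]
    g = [r.g for r in profiles]
    ax.plot(q, z, "^-", color="tab:blue", label="z (DAR)")
    ax.set_xlabel("diversity order q")
    ax.set_ylabel("scaling exponent z", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(q, g, "o-", color="tab:red", label="g (PDO)")
    ax2.set_ylabel("pairwise overlap g", color="tab:red")
    ax.set_title("DAR and PDO profiles")
    return ax


def _grouped_bars(profile_map: Mapping[str, DarProfileSet], attr: str,
                  ylabel: str, title: str, ax=None):
    ax = _get_ax(ax)
    labels = list(profile_map)
    q_grid = profile_map[labels[0]].q_grid
    width = 0.8 / max(1, len(labels))
    x = np.arange(len(q_grid))
    for k, label in enumerate(labels):
        vals = [getattr(r, attr) for r in profile_map[label]]
        ax.bar(x + k * width, vals, width=width, label=label)
    ax.set_xticks(x + width * (len(labels) - 1) / 2)
    ax.set_xticklabels([f"q={q:g}" for q in q_grid])
    ax.set_ylabel(ylabel)
    ax.set_title(title)
    ax.legend()
    return ax


def plot_mad(profile_map: Mapping[str, DarProfileSet], ax=None):
    """Maximal accrued diversity D_max(q) bars, one series per group."""
    return _grouped_bars(profile_map, "d_max", "D_max",
                         "MAD profile (maximal accrued diversity)", ax=ax)


def plot_lgd(profile_map: Mapping[str, DarProfileSet], ax=None):
    """Local-to-global diversity ratio LGD%(q) bars per group."""
    return _grouped_bars(profile_map, "lgd_percent", "LGD (%)",
                         "LGD profile (local / global diversity)", ax=ax)
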