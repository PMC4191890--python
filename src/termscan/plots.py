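"""Vector-graphic summaries: metagene profiles and readthrough rankings."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .metagene import ReadthroughRanking

# reproducible SVG output: stable element ids, no embedded date
matplotlib.rcParams["svg.hashsalt"] = "termscan"
_SAVE_KWARGS = {"metadata": {"Date": None}}


def plot_metagene(
    bin_offsets: np.ndarray,
    control_mean: np.ndarray,
    treated_mean: np.ndarray,
    path: str,
    title: str = "Metagene at termination points",
) -> None:
    """Mean occupancy per bin, control (dotted) vs depleted (solid)."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(bin_offsets, control_mean, linestyle=":", color="0.35", label="control")
    ax.plot(bin_offsets, treated_mean, linestyle="-", color="black", label="depleted")
    ax.axvline(0, color="0.8", linewidth=0.8)
    ax.set_xlabel("distance from anchor (nt, transcription 5'→3')")
    ax.set_ylabel("mean occupancy per base")
    ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, **_SAVE_KWARGS)
    plt.close(fig)


def plot_ranking(ranking: ReadthroughRanking, path: str,
                 title: str = "Percent readthrough, ranked") -> None:
    """Percent readthrough per terminator vs rank fraction."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.plot(ranking.rank_fraction, ranking.values, marker="o", markersize=2.5,
            linestyle="none", color="black")
    ax.axhline(0, color="0.8", linewidth=0.8)
    ax.set_xlabel("rank (fraction of terminators)")
    ax.set_ylabel("percent readthrough (depleted − control)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, **_SAVE_KWARGS)
    plt.close(fig)
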