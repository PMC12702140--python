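"""Per-residue track plots: 3-state propensities and entropy vs residue."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from foldswitch.scoring import ResidueScoreTrack


def plot_track(track: ResidueScoreTrack, path: str | Path) -> None:
    """Write a two-panel figure: propensity tracks on top, entropy below."""
    fig, (ax_p, ax_e) = plt.subplots(
        2, 1, sharex=True, figsize=(8, 5),
        gridspec_kw={"height_ratios": [2, 1]},
    )
    pos = track.positions
    ax_p.plot(pos, track.h, label="helix", color="tab:red")
    ax_p.plot(pos, track.e, label="strand", color="tab:blue")
    ax_p.plot(pos, track.l, label="loop", color="tab:green")
    ax_p.set_ylabel("propensity")
    ax_p.set_ylim(-0.05, 1.05)
    ax_p.legend(loc="upper right", fontsize="small")
    ax_p.set_title(track.protein_id)
    ax_e.plot(pos, track.entropy, color="black")
    ax_e.set_ylabel("entropy (nats)")
    ax_e.set_xlabel("residue number")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
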