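"""Per-chromosome copy-number plots.

Visual contract: gray dots for per-bin CN, a blue running-mean line along
the chromosome, red marks over masked (repetitive/excluded) regions and a
black box at the centromere; y axis fixed to [0, 4] copies.
"""

from __future__ import annotations

import numpy as np

from .profile import CopyNumberProfile

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_chromosome(
    profile: CopyNumberProfile, chrom: str, path: str, mean_window: int = 25
) -> None:
    g = profile.grid
    sl = g.chrom_slice(chrom)
    mid = (g.start[sl] + g.end[sl]) / 2e6  # Mb
    cn = profile.raw_cn[sl]
    fig, ax = plt.subplots(figsize=(8, 2.5))
    ax.plot(mid, cn, ".", color="0.6", ms=2, rasterized=True)
    ok = ~np.isnan(cn)
    if ok.sum() >= mean_window:
        kernel = np.ones(mean_window) / mean_window
        run = np.convolve(cn[ok], kernel, mode="same")
        ax.plot(mid[ok], run, color="tab:blue", lw=1.2)
    masked = g.mask[sl]
    if masked.any():
        ax.plot(mid[masked], np.full(masked.sum(), 3.9), "s", color="red", ms=2)
    if chrom in g.centromeres:
        s, e = g.centromeres[chrom]
        ax.add_patch(
            plt.Rectangle((s / 1e6, 0.0), (e - s) / 1e6, 0.15, color="black")
        )
    ax.set_ylim(0, 4)
    ax.set_xlabel(f"{chrom} position (Mb)")
    ax.set_ylabel("copy number")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_all_chromosomes(profile: CopyNumberProfile, out_dir: str) -> list[str]:
    import os

    paths = []
    for chrom in profile.grid.chroms:
        path = os.path.join(out_dir, f"cn_{chrom}.png")
        plot_chromosome(profile, chrom, path)
        paths.append(path)
    return paths
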