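"""Optional scan figures (matplotlib)."""

from __future__ import annotations


def scan_plot(track, intervals, path, level_col: str = "threshold") -> None:
    """Per-chromosome Δ(SNP-index) scatter with the loess line and threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(track["chrom"].unique())
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.6 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = track[track["chrom"] == chrom]
        mb = sub["pos"] / 1e6
        ax.scatter(mb, sub["delta"], s=2, alpha=0.3, color="grey")
        ax.plot(mb, sub["smoothed_delta"], color="C0", lw=1.5, label="loess")
        if level_col in sub:
            ax.plot(mb, sub[level_col], color="red", ls="--", lw=1, label="threshold")
        for iv in intervals:
            if iv.chrom == chrom:
                ax.axvspan(iv.start / 1e6, iv.end / 1e6, color="orange", alpha=0.15)
        ax.set_ylabel("Δ(SNP-index)")
        ax.set_title(chrom, fontsize=9)
        ax.set_ylim(-1, 1)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    axes.ravel()[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
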