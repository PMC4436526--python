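"""Surface-map plots for the exploratory all-pairs coupling analysis."""

from __future__ import annotations

from pathlib import Path

from .coupling import SurfaceMaps


def plot_surface_maps(maps: SurfaceMaps, out_path: str | Path | None = None):
    """Plot the 42x42 mean-r and mean-lag maps side by side.

    Rows are actor channels, columns imitator channels, tracker-major in
    canonical order; a strong diagonal marks matched-channel coupling.
    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(14, 6))
    for ax, (df, title, kw) in zip(
        axes,
        [
            (maps.r_map, "mean |r| at absolute maximum", dict(vmin=0, vmax=1, cmap="magma")),
            (maps.lag_map, "mean lag at maximum (s)", dict(vmin=-2, vmax=2, cmap="coolwarm")),
        ],
    ):
        im = ax.imshow(df.to_numpy(), origin="upper", **kw)
        ax.set_title(title)
        ax.set_xlabel("imitator channel")
        ax.set_ylabel("actor channel")
        ticks = range(0, len(df.columns), 6)
        ax.set_xticks(list(ticks), [df.columns[i] for i in ticks], rotation=90, fontsize=6)
        ax.set_yticks(list(ticks), [df.index[i] for i in ticks], fontsize=6)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
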